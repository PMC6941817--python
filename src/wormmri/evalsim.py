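"""Scoring and study paradigms: structural similarity, the three simulation
designs (body position, resolution ratio, prediction horizon) and the
imageability taxonomy.

Reconstructions are scored against the true slice phantom with the mean
local structural-similarity index (11x11 Gaussian window, sigma = 1.5,
stabilizers K1 = 0.01, K2 = 0.03); identical images score 1, structurally
unrelated images ~0 (negative values are clipped to 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .detect import TrackResult, track_video
from .mrisim import SequenceParams, reconstruct, run_gre, true_slice_image
from .synthgen import VideoDataset

__all__ = [
    "SimilarityResult",
    "ParadigmReport",
    "ssim",
    "score_acquisition",
    "simulation_body_position",
    "simulation_resolution",
    "simulation_horizon",
    "improvement_ratio",
    "classify_imageability",
]

SIM1_SLICES = (0.02, 0.5, 1.0)
SIM2_SLICE = 0.72
SIM2_RATIOS = (1, 2, 4)
SIM3_SLICE = 0.52
SIM3_HORIZONS = tuple(range(1, 11))
STAT_SLICES = (0.1, 0.3, 0.5, 0.9)   # four-slice statistical assessment


@dataclass(frozen=True)
class SimilarityResult:
    s_xy: float
    win_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03


@dataclass
class ParadigmReport:
    """Long-format condition table plus per-condition summary statistics."""

    table: pd.DataFrame   # columns: video, s, horizon, mode, ratio, ssim

    def summary(self, by: list[str]) -> pd.DataFrame:
        g = self.table.groupby(by)["ssim"]
        return g.agg(["mean", "std"]).reset_index()


def ssim(x: np.ndarray, y: np.ndarray,
         data_range: float | None = None) -> SimilarityResult:
    """Mean local structural similarity between two images.

    ``data_range`` defaults to 1 for images within the package's [0, 1]
    intensity convention, and otherwise to the joint intensity range of
    the two images — both symmetric in the arguments.  Negative global
    means are clipped to 0 so the score lives in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must have equal shapes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("images must be finite")
    if data_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        data_range = 1.0 if (lo >= 0.0 and hi <= 1.0) else float(hi - lo)
    val = structural_similarity(
        x, y, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
        data_range=data_range)
    return SimilarityResult(s_xy=float(np.clip(val, 0.0, 1.0)))


def score_acquisition(dataset: VideoDataset, s: float, horizon: int,
                      mode: str, ratio: int = 1,
                      track: TrackResult | None = None) -> float:
    """Run one acquisition and return SSIM against the true slice."""
    params = SequenceParams(horizon=horizon, mode=mode,
                            resolution_ratio=ratio)
    ks = run_gre(dataset, params, s, track=track)
    recon = reconstruct(ks).magnitude
    ref = true_slice_image(dataset, s, 0)
    return ssim(recon, ref).s_xy


def _tracks_for(datasets: list[VideoDataset],
                tracks: list[TrackResult] | None) -> list[TrackResult]:
    if tracks is not None:
        return tracks
    return [track_video(ds) for ds in datasets]


def simulation_body_position(datasets: list[VideoDataset],
                             tracks: list[TrackResult] | None = None
                             ) -> ParadigmReport:
    """Simulation 1: head (s=0.02), mid-body (s=0.5) and tail (s=1.0)
    slices at horizon 1, with and without prediction."""
    tracks = _tracks_for(datasets, tracks)
    rows = []
    for vid, (ds, tr) in enumerate(zip(datasets, tracks)):
        for s in SIM1_SLICES:
            for mode in ("prediction", "no_prediction"):
                val = score_acquisition(ds, s, 1, mode, track=tr)
                rows.append((vid, s, 1, mode, 1, val))
    return ParadigmReport(table=pd.DataFrame(
        rows, columns=["video", "s", "horizon", "mode", "ratio", "ssim"]))


def simulation_resolution(dataset: VideoDataset,
                          track: TrackResult | None = None) -> ParadigmReport:
    """Simulation 2: mid-body slice s=0.72 at MR:optical resolution ratios
    1:1, 2:1 and 4:1, horizon 1, both modes."""
    if track is None:
        track = track_video(dataset)
    rows = []
    for ratio in SIM2_RATIOS:
        for mode in ("prediction", "no_prediction"):
            val = score_acquisition(dataset, SIM2_SLICE, 1, mode,
                                    ratio=ratio, track=track)
            rows.append((0, SIM2_SLICE, 1, mode, ratio, val))
    return ParadigmReport(table=pd.DataFrame(
        rows, columns=["video", "s", "horizon", "mode", "ratio", "ssim"]))


def simulation_horizon(datasets: list[VideoDataset],
                       tracks: list[TrackResult] | None = None,
                       slices: tuple[float, ...] = (SIM3_SLICE,),
                       horizons: tuple[int, ...] = SIM3_HORIZONS
                       ) -> ParadigmReport:
    """Simulation 3: SSIM versus prediction horizon (1..10 frames), with
    and without prediction; optionally over several slice positions."""
    tracks = _tracks_for(datasets, tracks)
    rows = []
    for vid, (ds, tr) in enumerate(zip(datasets, tracks)):
        for s in slices:
            for dk in horizons:
                for mode in ("prediction", "no_prediction"):
                    val = score_acquisition(ds, s, dk, mode, track=tr)
                    rows.append((vid, s, dk, mode, 1, val))
    return ParadigmReport(table=pd.DataFrame(
        rows, columns=["video", "s", "horizon", "mode", "ratio", "ssim"]))


def improvement_ratio(report: ParadigmReport) -> float:
    """Mean SSIM with prediction over mean SSIM without, across all
    conditions of a horizon report (the four-slice statistical design)."""
    t = report.table
    pred = t[t["mode"] == "prediction"]["ssim"].mean()
    nopred = t[t["mode"] == "no_prediction"]["ssim"].mean()
    return float(pred / nopred)


def classify_imageability(t_motion: float, t_pred: float, tr: float) -> str:
    """Place a sample in the motion / prediction / sequence time-scale
    taxonomy.

    * ``t_motion < TR``: ``not_imageable`` — the object moves faster than a
      single spatial-encoding period; motion must be slowed first.
    * ``TR < t_motion`` but ``TR < t_pred``: ``imageable_contrast_restricted``
      — imaging works, but TE/TR must be chosen so the prediction finishes
      inside TR, restricting the available contrast weightings.
    * ``t_pred < TR < t_motion``: ``imageable_unrestricted``.

    All times in the same unit (ms).
    """
    if t_motion <= 0 or t_pred <= 0 or tr <= 0:
        raise ValueError("all time scales must be positive")
    if t_motion < tr:
        return "not_imageable"
    if t_pred >= tr:
        return "imageable_contrast_restricted"
    return "imageable_unrestricted"
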