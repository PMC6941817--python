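"""Motion prediction along the worm: future COG and POI positions.

The central model: body segments (head excluded) move along the current
centerline, each following its predecessor at the worm speed, so a point of
interest at coordinate ``s`` will after ``dk`` frames occupy the spatial
position of the point currently at ``s_c = s - v * dk`` (clamped to the
head, s = 0, when the horizon overshoots the body).  The COG itself moves
approximately linearly and is extrapolated from its past five positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import Skeleton, TrackResult, locate_poi

__all__ = [
    "PoiPrediction",
    "PredictionErrorReport",
    "predict_cog",
    "predict_poi",
    "evaluate_prediction",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoiPrediction:
    s: float                 # current coordinate of the POI
    s_c: float               # predicted coordinate after delta_k frames
    delta_k: int
    position: np.ndarray     # predicted point on the *current* skeleton


@dataclass
class PredictionErrorReport:
    """Euclidean distances between predicted and actual POI positions."""

    distances: np.ndarray        # per evaluated frame, um
    frames: np.ndarray           # frame index the prediction was made at
    s: float
    delta_k: int

    @property
    def mean_prediction_error(self) -> float:
        return float(np.mean(self.distances))


def predict_cog(history: list | np.ndarray, delta_k: int) -> np.ndarray:
    """Linear extrapolation of the COG from its past <= 5 positions.

    Least-squares line fit per coordinate against frame index, evaluated
    ``delta_k`` frames ahead; robust to pixel quantization compared with a
    two-point slope.  A single-point history is returned unchanged.
    """
    hist = np.asarray(history, dtype=float)
    if hist.ndim != 2 or hist.shape[1] != 2:
        raise ValueError("history must be a sequence of 2D points")
    hist = hist[-5:]
    n = len(hist)
    if n == 1:
        return hist[0].copy()
    t = np.arange(n, dtype=float)
    out = np.empty(2)
    for d in range(2):
        slope, intercept = np.polyfit(t, hist[:, d], 1)
        out[d] = slope * (n - 1 + delta_k) + intercept
    return out


def predict_poi(skel: Skeleton, s: float, v: float, delta_k: int) -> PoiPrediction:
    """Predicted POI coordinate and position: ``s_c = s - v * delta_k``.

    ``v`` is in normalized s-units per frame.  Negative predictions clamp
    to the head (s = 0); an upper clamp at s = 1 covers backward motion and
    is flagged in the log.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s={s} outside [0, 1]")
    if v < 0:
        raise ValueError("v must be non-negative")
    if delta_k < 0:
        raise ValueError("delta_k must be non-negative")
    s_c = s - v * delta_k
    if s_c > 1.0:
        log.warning("predicted coordinate %.3f clamped to tail", s_c)
        s_c = 1.0
    s_c = max(0.0, s_c)
    return PoiPrediction(s=s, s_c=s_c, delta_k=delta_k,
                         position=locate_poi(skel, s_c))


def evaluate_prediction(track: TrackResult, s: float,
                        delta_k: int) -> PredictionErrorReport:
    """Score the POI predictor over a tracked video.

    For every frame ``k`` with a valid skeleton at ``k`` and ``k + delta_k``
    the position predicted at ``k`` for ``k + delta_k`` is compared with the
    tracked POI position at ``k + delta_k``; distances are reported in
    micrometres and averaged into the mean prediction error.
    """
    if track.n_frames <= delta_k:
        raise ValueError("video shorter than the prediction horizon")
    dists, frames = [], []
    for k in range(track.n_frames - delta_k):
        skel_now = track.skeletons[k]
        skel_fut = track.skeletons[k + delta_k]
        if skel_now is None or skel_fut is None:
            continue
        pred = predict_poi(skel_now, s, track.velocities[k], delta_k)
        p_pred = track.to_world(pred.position)
        p_true = track.to_world(locate_poi(skel_fut, s))
        dists.append(float(np.linalg.norm(p_pred - p_true)))
        frames.append(k)
    if not dists:
        raise ValueError("no frames with valid tracking to evaluate")
    return PredictionErrorReport(distances=np.asarray(dists),
                                 frames=np.asarray(frames), s=s,
                                 delta_k=delta_k)
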