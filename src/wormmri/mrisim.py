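"""Gradient-echo Cartesian MR acquisition of a slice of the moving worm.

One k-space line is acquired per repetition time TR, which is locked to the
video frame interval; between lines the gradient centre G_C is updated —
either following the center-line predictor, held fixed (no prediction), or
placed from the ground-truth pose (oracle).  Motion within a single line is
ignored (short-TE assumption), so each line is one row of the centred 2D
discrete Fourier transform of the field-of-view image at that line's
acquisition frame.

Encoding model
--------------
Every FoV voxel contributes ``intensity * exp(-i [phi_J * xi_idx +
omega_m * eta_idx])`` with the phase-encode step ``phi_J = -pi + J*2pi/N``
(J = 1..N) along the in-plane axis xi and the readout frequency along eta;
a uniform-sensitivity virtual coil sums all voxels.  No relaxation, no
off-resonance.  Line J therefore equals the centred-DFT row of spatial
frequency J - N/2 (J = N aliases to the most negative frequency, -N/2, the
two being identical on the integer grid).

Gradient-centre error model
---------------------------
The predictor works in the video plane, so the G_C error is a 2D vector
decomposed in the local frame of the true slice: the along-body component
selects which 24-um slab actually lies in the FoV (neighbouring-slice
substitution), the in-plane component shifts the cross-section along xi
with zero filling.  The out-of-plane axis eta carries no error.  The
in-plane error converts to voxels through the optical-pixel-to-voxel
correspondence of the study design: at a 1:1 MR:optical resolution ratio
one pixel of (downsampled) tracking-video error is one voxel of k-space
error, at 2:1 two voxels, at 4:1 four.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift

from .detect import DOWNSAMPLE_FACTOR, TrackResult, track_video
from .predict import predict_poi
from .synthgen import VideoDataset

__all__ = [
    "SequenceParams",
    "SlicePlan",
    "KSpace",
    "ReconImage",
    "slab_index_of",
    "true_slice_image",
    "observed_fov_image",
    "encode_line",
    "run_gre",
    "reconstruct",
]

MODES = ("prediction", "no_prediction", "oracle", "static")


@dataclass(frozen=True)
class SequenceParams:
    """Gradient-echo sequence settings.

    TR defaults to 83 ms, matching the 12 Hz video cadence (one line per
    frame); TE = 4 ms is bookkeeping only since intra-line motion is
    ignored.  ``resolution_ratio`` is the MR : optical resolution ratio.
    """

    tr_ms: float = 83.0
    te_ms: float = 4.0
    n_lines: int = 64
    n_readout: int = 64
    horizon: int = 1           # frames, 1..10 in the study design
    slice_step: float = 0.02   # delta-s when stepping through slices
    mode: str = "prediction"
    resolution_ratio: int = 1  # 1, 2 or 4
    gc_smoothing: float = 0.4  # EMA weight for the gradient-centre
                               # trajectory (1 = no smoothing); mirrors the
                               # first-order low-pass of the tracked COG

    def __post_init__(self) -> None:
        if not 0 < self.te_ms < self.tr_ms:
            raise ValueError("need 0 < TE < TR")
        if self.n_lines < 1 or self.n_readout < 1:
            raise ValueError("need at least one line / readout sample")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "prediction" and self.horizon < 1:
            raise ValueError("prediction mode needs horizon >= 1")
        if self.resolution_ratio < 1:
            raise ValueError("resolution_ratio must be >= 1")


@dataclass(frozen=True)
class SlicePlan:
    """Per-line imaging geometry: gradient centre plus slice-plane axes.

    xi (phase encode) lies in the video plane perpendicular to the local
    centerline tangent, eta (frequency encode) is the out-of-plane axis;
    both are unit 3-vectors with xi . eta = 0.
    """

    target_s: float
    g_c: np.ndarray            # (2,) world um, in the video plane
    slab_normal: np.ndarray    # (2,) unit, along the body (tangent)
    xi: np.ndarray             # (3,) unit
    eta: np.ndarray            # (3,) unit
    fov_resolution: float      # um / voxel along xi

    def __post_init__(self) -> None:
        if abs(float(self.xi @ self.eta)) > 1e-9:
            raise ValueError("xi and eta must be orthogonal")


@dataclass
class KSpace:
    lines: np.ndarray          # (N, M) complex
    filled: np.ndarray         # (N,) bool

    @classmethod
    def empty(cls, n_lines: int, n_readout: int) -> "KSpace":
        return cls(lines=np.zeros((n_lines, n_readout), dtype=complex),
                   filled=np.zeros(n_lines, dtype=bool))

    @property
    def n_lines(self) -> int:
        return self.lines.shape[0]

    @property
    def complete(self) -> bool:
        return bool(self.filled.all())


@dataclass
class ReconImage:
    magnitude: np.ndarray      # (N, M) non-negative


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def slab_index_of(s: float, n_slices: int = 50) -> int:
    """1-based slab containing coordinate ``s``; slab k covers
    ((k-1)/n, k/n], boundaries belong to the lower-index slab, s = 0 to
    slab 1."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s={s} outside [0, 1]")
    k = int(np.ceil(s * n_slices - 1e-12))
    return min(max(k, 1), n_slices)


def make_slice_plan(dataset: VideoDataset, s: float, g_c: np.ndarray,
                    frame: int, resolution_ratio: int = 1) -> SlicePlan:
    """Slice-plane frame at the predicted position: xi in the video plane
    perpendicular to the centerline tangent, eta out of plane."""
    pose = dataset.poses[frame]
    t = pose.tangent_at(s)
    normal2 = np.array([-t[1], t[0]])
    res = dataset.phantoms[0].in_plane_resolution / resolution_ratio
    return SlicePlan(
        target_s=s,
        g_c=np.asarray(g_c, dtype=float),
        slab_normal=np.array([t[0], t[1]]),
        xi=np.array([normal2[0], normal2[1], 0.0]),
        eta=np.array([0.0, 0.0, 1.0]),
        fov_resolution=res,
    )


def true_slice_image(dataset: VideoDataset, s: float, frame: int) -> np.ndarray:
    """Reference cross section at coordinate ``s``: the phantom of the slab
    containing ``s`` (the phantom library defines in-plane appearance; the
    pose only positions and orients it, so the image is frame-invariant)."""
    if not 0 <= frame < dataset.n_frames:
        raise ValueError(f"frame {frame} out of range")
    k = slab_index_of(s, len(dataset.phantoms))
    return dataset.phantoms[k - 1].intensities.copy()


def observed_fov_image(dataset: VideoDataset, plan: SlicePlan,
                       frame: int, resolution_ratio: int = 1) -> np.ndarray:
    """Cross-section actually seen by a FoV centred at ``plan.g_c`` while
    the worm is in the pose of ``frame``.

    The G_C error relative to the true slice is decomposed in the true
    slice frame of that pose: the along-body component re-selects the slab
    (>= half a slab thickness away lands in the neighbouring slice, outside
    the body yields zeros), the in-plane component shifts the phantom along
    xi with zero fill, amplified by the resolution ratio.
    """
    if not 0 <= frame < dataset.n_frames:
        raise ValueError(f"frame {frame} out of range")
    pose = dataset.poses[frame]
    n_slices = len(dataset.phantoms)
    s0 = plan.target_s
    c_true = pose.point_at(s0)
    t_hat = pose.tangent_at(s0)
    n_hat = np.array([-t_hat[1], t_hat[0]])
    err = plan.g_c - c_true

    along = float(err @ t_hat)                 # um toward the tail
    s_gc = s0 + along / pose.length
    if s_gc < -0.5 / n_slices or s_gc > 1.0 + 0.5 / n_slices:
        return np.zeros((64, 64))
    k = slab_index_of(float(np.clip(s_gc, 0.0, 1.0)), n_slices)
    phantom = dataset.phantoms[k - 1].intensities

    # voxel conversion: one optical-video pixel of prediction error maps to
    # ``resolution_ratio`` voxels of k-space error (the tracking video is
    # the 9x-downsampled recording)
    in_plane = float(err @ n_hat)              # um along xi
    optical_px = dataset.pixel_size * DOWNSAMPLE_FACTOR
    shift_vox = in_plane * resolution_ratio / optical_px
    if abs(shift_vox) < 1e-12:
        return phantom.copy()
    if abs(shift_vox) >= phantom.shape[0]:
        return np.zeros_like(phantom)
    # content moves opposite to the FoV displacement; rows leaving the FoV
    # are replaced by zeros
    return nd_shift(phantom, (-shift_vox, 0.0), order=1, mode="constant",
                    cval=0.0, prefilter=False)


# --------------------------------------------------------------------------
# encoding / acquisition / reconstruction
# --------------------------------------------------------------------------

def _phase_encode_angle(J: int, n_lines: int) -> float:
    """phi_J = -pi + J * 2pi / N, the per-voxel-index phase step of line J."""
    return -np.pi + J * 2.0 * np.pi / n_lines


def encode_line(fov: np.ndarray, J: int, kspace: KSpace) -> np.ndarray:
    """Fill line ``J`` (1-based): the uniform-coil sum of all voxel signals
    after phase encoding along xi (rows) and frequency encoding along eta
    (columns); equals the centred-DFT row of frequency J - N/2."""
    N, M = kspace.lines.shape
    if not 1 <= J <= N:
        raise ValueError(f"line index {J} outside 1..{N}")
    if fov.ndim != 2 or fov.shape[1] != M:
        raise ValueError("FoV image width must match the readout length")
    n_rows = fov.shape[0]
    ci, cj = n_rows // 2, M // 2
    phi = _phase_encode_angle(J, N)
    pe = np.exp(-1j * phi * (np.arange(n_rows) - ci))
    fe = np.exp(-2j * np.pi
                * np.outer(np.arange(M) - cj, np.arange(M) - cj) / M)
    line = (pe @ fov) @ fe
    kspace.lines[J - 1] = line
    kspace.filled[J - 1] = True
    return line


def _resolve_g_c(dataset: VideoDataset, params: SequenceParams, s: float,
                 frame: int, start_frame: int,
                 track: TrackResult | None) -> np.ndarray:
    """Gradient centre for the line acquired at ``frame``."""
    mode = params.mode
    if mode == "oracle":
        return dataset.poses[frame].point_at(s)
    if mode in ("static",):
        return dataset.poses[start_frame].point_at(s)
    if mode == "no_prediction":
        # fixed at the true slice position at the first acquisition frame,
        # i.e. the position of the slice after `horizon` frames of motion
        return dataset.poses[start_frame].point_at(s)
    # prediction: made horizon frames before this line's acquisition
    assert track is not None
    kp = frame - params.horizon
    skel = track.skeletons[kp]
    if skel is None:
        raise RuntimeError(f"detection failed at frame {kp}")
    poi = predict_poi(skel, s, track.velocities[kp], params.horizon)
    return track.to_world(poi.position)


def run_gre(dataset: VideoDataset, params: SequenceParams, s: float,
            track: TrackResult | None = None,
            start_frame: int | None = None) -> KSpace:
    """Acquire a full k-space of the slice at coordinate ``s``.

    Line J is acquired at frame ``start_frame + J - 1`` (one line per TR =
    one video frame).  ``start_frame`` defaults to the prediction horizon so
    every line's prediction can be made from already-tracked frames; static
    mode freezes the worm at the start frame, making the acquisition the
    exact forward DFT of the true slice.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s={s} outside [0, 1]")
    f0 = start_frame if start_frame is not None else (
        0 if params.mode == "static" else params.horizon)
    last_needed = f0 + (0 if params.mode == "static" else params.n_lines - 1)
    if last_needed >= dataset.n_frames:
        raise ValueError(
            f"video too short: need {last_needed + 1} frames, "
            f"have {dataset.n_frames}")
    if params.mode == "prediction" and track is None:
        track = track_video(dataset)

    ks = KSpace.empty(params.n_lines, params.n_readout)
    ema_pos: np.ndarray | None = None
    ema_step: np.ndarray | None = None
    prev_raw: np.ndarray | None = None
    for J in range(1, params.n_lines + 1):
        frame = f0 if params.mode == "static" else f0 + J - 1
        g_c = _resolve_g_c(dataset, params, s, frame, f0, track)
        if params.mode == "prediction" and params.gc_smoothing < 1.0:
            # causal low-pass of the gradient-centre trajectory to suppress
            # line-to-line tracking noise; the smoothed per-line step is fed
            # forward to cancel the filter's lag behind the sliding slice
            a = params.gc_smoothing
            b = 0.15   # slow trend gain so the lag term stays noise-free
            if ema_pos is None:
                ema_pos = g_c.copy()
                ema_step = np.zeros(2)
            else:
                ema_pos = a * g_c + (1.0 - a) * ema_pos
                ema_step = b * (g_c - prev_raw) + (1.0 - b) * ema_step
            prev_raw = g_c.copy()
            g_c = ema_pos + (1.0 - a) / a * ema_step
        plan = make_slice_plan(dataset, s, g_c, frame,
                               params.resolution_ratio)
        if params.mode == "static":
            fov = true_slice_image(dataset, s, f0)
        else:
            fov = observed_fov_image(dataset, plan, frame,
                                     params.resolution_ratio)
        encode_line(fov, J, ks)
    return ks


def reconstruct(kspace: KSpace) -> ReconImage:
    """Magnitude of the centred inverse 2D DFT of the acquired k-space."""
    N, M = kspace.lines.shape
    centered = np.zeros_like(kspace.lines)
    for J in range(1, N + 1):
        centered[J % N] = kspace.lines[J - 1]
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(centered)))
    return ReconImage(magnitude=np.abs(img))
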