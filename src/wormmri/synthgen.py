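"""Synthetic worm videos with exact ground truth, plus the slice-phantom library.

Generates bright-field-like recordings of a single crawling C. elegans with
known centerline poses, and a stack of 50 MR-like cross-sectional phantoms
(64x64) attached to the body.  These stand in for real microscope videos and
a transmission-EM slice stack, and give the tracking / MRI-simulation layers
a ground truth to be scored against.

Conventions (used everywhere in this package):
  * world coordinates in micrometres, ``(x, y)`` with y pointing down;
  * images are row-major arrays indexed ``[row, col]`` = ``[y, x]``,
    0-based, origin at the top-left; pixel ``(r, c)`` has its centre at
    ``origin_um + ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)``;
  * intensities live in ``[0, 1]``.

Worm kinematics
---------------
The real recordings the pipeline is designed for are Petri-dish crawls: the
worm propagates a dorsoventral bend wave backwards along its body and, to a
good approximation, each body segment follows the track laid down by its
predecessor.  The generator reproduces exactly that situation:

  * the head anchor advances at ``speed`` along a slowly drifting heading;
  * the body is a travelling sine wave behind the head, propagating
    backwards along the body; at the default 0.3 Hz bend frequency the
    wave runs faster than the worm advances (substrate slip, as on soft
    gel), so the predecessor-following assumption the predictor relies on
    holds approximately rather than exactly;
  * the undulation amplitude tapers to zero over the first quarter of the
    body; head motion is instead supplied by an independent high-frequency
    random casting deflection of the anterior quarter (full strength over
    the first 10 % of arc length), emulating the erratic exploratory head
    swings of a foraging worm — the fastest-moving part of the animal.

All poses are arc-length parametrised (``s = 0`` head, ``s = 1`` tail) and
resampled so that total arc length equals ``body_length`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "WormKinematics",
    "CenterlinePose",
    "FrameImage",
    "SlicePhantom",
    "SliceGeometry",
    "VideoDataset",
    "KinematicTrace",
    "make_trace",
    "generate_centerline",
    "render_frame",
    "make_background",
    "default_width_profile",
    "generate_phantom_sources",
    "invert_intensities",
    "build_slice_phantoms",
    "slice_worm",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "resample_area",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WormKinematics:
    """Ground-truth kinematic parameters of one synthetic recording.

    Defaults reproduce the study conditions of the recordings the pipeline
    emulates: a 1.2 mm adult crawling at ~0.13 mm/s, filmed at 12 Hz for
    10 s.  Undulation amplitude, wavelength and frequency are free
    parameters of the generator, defaulted to typical crawl values; the
    default 0.3 Hz bend frequency exceeds ``speed / wavelength``
    (~0.18 Hz), i.e. the worm slips against its gel substrate as real
    crawlers do, so body segments follow their predecessors approximately
    but not exactly.
    Setting ``undulation_frequency=None`` selects the exact track-following
    frequency ``speed / wavelength`` (no slip).
    """

    body_length: float = 1200.0          # um
    speed: float = 130.0                 # um / s
    undulation_amplitude: float = 100.0  # um, lateral half-amplitude
    undulation_wavelength: float = 720.0  # um (~0.6 body lengths)
    undulation_frequency: float | None = 0.3  # Hz; None -> speed/wavelength
    head_jitter_std: float = 0.25        # rad per frame
    frame_rate: float = 12.0             # Hz
    duration: float = 10.0               # s
    heading_drift_std: float = 0.02      # rad per frame
    seed: int = 0
    max_half_width: float = 40.0         # um, mid-body half thickness

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.undulation_amplitude < 0:
            raise ValueError("undulation_amplitude must be non-negative")
        if self.undulation_wavelength <= 0:
            raise ValueError("undulation_wavelength must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    @property
    def frequency(self) -> float:
        """Temporal undulation frequency in Hz."""
        if self.undulation_frequency is not None:
            return self.undulation_frequency
        return self.speed / self.undulation_wavelength


@dataclass
class CenterlinePose:
    """Ground-truth centerline of one frame: ordered head->tail, uniform in
    arc length, positions in um."""

    timestamp: int
    points: np.ndarray          # (n, 2) columns (x, y) um
    width_profile: np.ndarray   # (n,) half-width um

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.width_profile = np.asarray(self.width_profile, dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length per node, starting at 0 (head)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Position of the normalized coordinate ``s`` in [0, 1]."""
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"s={s} outside [0, 1]")
        arcs = self.arc_lengths()
        target = s * arcs[-1]
        x = np.interp(target, arcs, self.points[:, 0])
        y = np.interp(target, arcs, self.points[:, 1])
        return np.array([x, y])

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent (pointing head -> tail) at coordinate ``s``."""
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"s={s} outside [0, 1]")
        arcs = self.arc_lengths()
        target = s * arcs[-1]
        i = int(np.clip(np.searchsorted(arcs, target) - 1, 0, len(arcs) - 2))
        d = self.points[i + 1] - self.points[i]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0])

    def width_at(self, s: float) -> float:
        arcs = self.arc_lengths()
        return float(np.interp(s * arcs[-1], arcs, self.width_profile))


@dataclass
class FrameImage:
    """One video frame.  ``origin_um`` is the world position of the image's
    top-left corner (pixel (0,0) centre sits half a pixel inside)."""

    pixels: np.ndarray       # (H, W) float in [0, 1]
    pixel_size: float        # um / pixel
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def world_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Map world um -> fractional (row, col)."""
        xy = np.asarray(xy, dtype=float)
        col = (xy[..., 0] - self.origin_um[0]) / self.pixel_size - 0.5
        row = (xy[..., 1] - self.origin_um[1]) / self.pixel_size - 0.5
        return np.stack([row, col], axis=-1)


@dataclass
class SlicePhantom:
    """64x64 MR-like cross section attached to one of the 50 body slabs."""

    intensities: np.ndarray      # (64, 64) in [0, 1], background exactly 0
    slice_index: int             # 1-based
    s_center: float              # normalized coordinate of the slab centre
    in_plane_resolution: float = 1.6  # um / voxel

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (64, 64):
            raise ValueError("slice phantom must be 64x64")


@dataclass(frozen=True)
class SliceGeometry:
    """Centre and local frame of one perpendicular body slab."""

    center: np.ndarray        # (2,) um
    tangent: np.ndarray       # (2,) unit, head -> tail
    normal: np.ndarray        # (2,) unit, in the video plane, tangent x 90deg
    s_center: float
    thickness: float          # um along the body


@dataclass
class VideoDataset:
    """A full synthetic recording: frames + ground-truth poses + phantoms."""

    frames: list[FrameImage]
    poses: list[CenterlinePose]
    phantoms: list[SlicePhantom]
    kinematics: WormKinematics

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.poses):
            raise ValueError("frames and poses must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    @property
    def origin_um(self) -> tuple[float, float]:
        return self.frames[0].origin_um


# --------------------------------------------------------------------------
# kinematic trace and centerline generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicTrace:
    """Per-video random draws, fixed once so that frames are addressable
    independently and the whole video is reproducible from the seed."""

    headings: np.ndarray       # (n_frames,) rad
    anchors: np.ndarray        # (n_frames, 2) head anchor positions, um
    head_jitter: np.ndarray    # (n_frames,) rad
    phase0: float              # rad, undulation phase offset


def make_trace(kin: WormKinematics, rng: np.random.Generator | None = None) -> KinematicTrace:
    rng = np.random.default_rng(kin.seed) if rng is None else rng
    n = kin.n_frames
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    drift = rng.normal(0.0, kin.heading_drift_std, size=n)
    headings = theta0 + np.concatenate([[0.0], np.cumsum(drift[:-1])])
    step = kin.speed / kin.frame_rate
    dirs = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    anchors = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(step * dirs[:-1], axis=0)], axis=0
    )
    jitter = rng.normal(0.0, kin.head_jitter_std, size=n)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return KinematicTrace(headings=headings, anchors=anchors,
                          head_jitter=jitter, phase0=phase0)


def default_width_profile(s: np.ndarray, max_half_width: float = 40.0) -> np.ndarray:
    """Half-width along the body: blunt rounded head, long whip-like tail.

    Anterior ramp saturates within the first few percent of arc length
    (the nose is nearly full thickness), the posterior third tapers
    quadratically to a fine tail tip; floored so the extreme tips stay
    visible at typical optics.
    """
    s = np.asarray(s, dtype=float)
    head = 1.0 - 0.35 * np.exp(-s / 0.03)   # blunt cap: ~65 % thickness at the nose
    tail = np.where(s > 0.8, 1.0 - ((s - 0.8) / 0.2) ** 2, 1.0)
    return np.maximum(max_half_width * head * tail, 5.0)


_AMP_RAMP_FRACTION = 0.25   # amplitude reaches full value at 25 % of the body
_JITTER_FRACTION = 0.10     # anterior fraction rotated by the head jitter


def generate_centerline(
    kin: WormKinematics,
    frame: int,
    trace: KinematicTrace | None = None,
    n_points: int = 200,
) -> CenterlinePose:
    """Ground-truth pose for one frame.

    The curve is built in the body-local frame (head at the origin, body
    along -x), given its travelling-wave lateral offset, resampled to
    uniform arc length with total length exactly ``body_length``, then
    rotated to the frame's heading and translated to the head anchor.
    """
    if frame < 0 or frame >= kin.n_frames:
        raise ValueError(f"frame {frame} outside [0, {kin.n_frames})")
    if trace is None:
        trace = make_trace(kin)
    L = kin.body_length
    t = frame / kin.frame_rate

    # fine sampling along the body axis; arc length >= axis length, so the
    # axis window [0, L] always contains >= L of arc
    u = np.linspace(0.0, L, 8 * n_points)
    ramp = np.clip(u / (_AMP_RAMP_FRACTION * L), 0.0, 1.0)
    env = np.sin(0.5 * np.pi * ramp) ** 2
    phase = 2.0 * np.pi * u / kin.undulation_wavelength \
        - 2.0 * np.pi * kin.frequency * t + trace.phase0
    x = -u
    y = env * kin.undulation_amplitude * np.sin(phase)

    # erratic head casting: independent per-frame lateral deflection of the
    # anterior quarter, full strength over the first 10 % of arc length and
    # blending smoothly to zero at the pivot (s = 0.25); the deflection of a
    # point is its jitter angle times the lever arm to the pivot
    j = trace.head_jitter[frame]
    if abs(j) > 0:
        u_p = _AMP_RAMP_FRACTION * L
        blend = np.clip((u_p - u) / (u_p - _JITTER_FRACTION * L), 0.0, 1.0)
        blend = blend * blend * (3.0 - 2.0 * blend)   # smoothstep
        blend = np.where(u <= _JITTER_FRACTION * L, 1.0, blend)
        y = y + j * (u_p - u) * blend

    seg = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, L, n_points)
    if arc[-1] < L:  # numerically impossible unless amplitude ~ 0
        targets = np.linspace(0.0, arc[-1], n_points) * (L / arc[-1])
        targets[-1] = min(targets[-1], arc[-1])
    xs = np.interp(targets, arc, x)
    ys = np.interp(targets, arc, y)
    pts = np.stack([xs, ys], axis=1)

    theta = trace.headings[frame]
    c, s_ = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s_], [s_, c]])
    pts = pts @ rot.T + trace.anchors[frame]

    s_norm = targets / L
    widths = default_width_profile(s_norm, kin.max_half_width)
    return CenterlinePose(timestamp=frame, points=pts, width_profile=widths)


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------

def make_background(
    shape: tuple[int, int],
    rng: np.random.Generator,
    level: float = 0.75,
    texture_std: float = 0.03,
    texture_scale_px: float = 15.0,
) -> np.ndarray:
    """Static bright background with smooth low-contrast texture."""
    tex = gaussian_filter(rng.normal(size=shape), sigma=texture_scale_px)
    sd = tex.std()
    if sd > 0:
        tex = tex / sd * texture_std
    return np.clip(level + tex, 0.0, 1.0).astype(np.float32)


def render_frame(
    pose: CenterlinePose,
    pixel_size: float,
    shape: tuple[int, int],
    background: np.ndarray,
    origin_um: tuple[float, float] = (0.0, 0.0),
    noise_std: float = 0.02,
    worm_intensity: float = 0.25,
    rng: np.random.Generator | None = None,
) -> FrameImage:
    """Rasterize the worm as a dark tube of ``width_profile`` on the static
    bright background, with additive Gaussian sensor noise.

    Raises ``ValueError`` if any centerline point maps outside the image.
    """
    if background.shape != shape:
        raise ValueError("background shape mismatch")
    H, W = shape
    px = (pose.points - np.asarray(origin_um)) / pixel_size  # (x, y) in px
    if pose.n_points:
        if (px[:, 0].min() < 0 or px[:, 1].min() < 0
                or px[:, 0].max() >= W or px[:, 1].max() >= H):
            raise ValueError("centerline leaves the field of view")

    out = background.astype(np.float32).copy()
    if pose.n_points:
        # dense resampling so nearest-node distance approximates distance to
        # the continuous centerline
        arcs = pose.arc_lengths()
        step = max(1.0, pixel_size / 2.0)
        dense_t = np.arange(0.0, arcs[-1] + step, step)
        dx = np.interp(dense_t, arcs, pose.points[:, 0])
        dy = np.interp(dense_t, arcs, pose.points[:, 1])
        dw = np.interp(dense_t, arcs, pose.width_profile)
        dense = np.stack([dx, dy], axis=1)

        wmax = float(pose.width_profile.max())
        pad = wmax / pixel_size + 2.0
        c0 = max(int(np.floor(px[:, 0].min() - pad)), 0)
        c1 = min(int(np.ceil(px[:, 0].max() + pad)) + 1, W)
        r0 = max(int(np.floor(px[:, 1].min() - pad)), 0)
        r1 = min(int(np.ceil(px[:, 1].max() + pad)) + 1, H)

        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        cx = origin_um[0] + (cols + 0.5) * pixel_size
        cy = origin_um[1] + (rows + 0.5) * pixel_size
        gx, gy = np.meshgrid(cx, cy)
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        dist, idx = cKDTree(dense).query(pts, workers=-1)
        cover = np.clip((dw[idx] - dist) / pixel_size + 0.5, 0.0, 1.0)
        cover = cover.reshape(len(rows), len(cols)).astype(np.float32)
        patch = out[r0:r1, c0:c1]
        out[r0:r1, c0:c1] = patch * (1.0 - cover) + worm_intensity * cover

    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        out = out + rng.normal(0.0, noise_std, size=shape).astype(np.float32)
    out = np.clip(out, 0.0, 1.0)
    return FrameImage(pixels=out, pixel_size=pixel_size, origin_um=origin_um)


# --------------------------------------------------------------------------
# slice phantoms
# --------------------------------------------------------------------------

def resample_area(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Exact area-weighted (block-average) resampling to ``out_shape``.

    Integrates the image over each output cell via linear interpolation of
    the cumulative sum along each axis; for integer downsampling factors
    this reduces to plain block averaging.
    """

    def rebin_axis(a: np.ndarray, m: int) -> np.ndarray:
        n = a.shape[0]
        cs = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)])
        edges = np.linspace(0.0, n, m + 1)
        i = np.clip(np.floor(edges).astype(int), 0, n)
        f = edges - i
        lo = np.minimum(i, n - 1)
        vals = cs[i] + f.reshape((-1,) + (1,) * (a.ndim - 1)) * a[lo]
        integ = np.diff(vals, axis=0)
        width = np.diff(edges).reshape((-1,) + (1,) * (a.ndim - 1))
        return integ / width

    out = rebin_axis(np.asarray(img, dtype=float), out_shape[0])
    out = rebin_axis(out.swapaxes(0, 1), out_shape[1]).swapaxes(0, 1)
    return out


def invert_intensities(img: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    """Invert the colour map inside the body; background fixed at 0.

    Bright (low-density) source regions become dark, as they would in a
    proton-density MR image.  Applying the inversion twice restores the
    background-removed source.
    """
    return np.where(body_mask, 1.0 - img, 0.0)


def build_slice_phantoms(
    source_images: Sequence[np.ndarray],
    n_slices: int = 50,
    bg_threshold: float = 0.95,
    in_plane_resolution: float = 1.6,
) -> list[SlicePhantom]:
    """Turn a stack of bright-background cross-section images into the
    64x64 phantom library: remove background, invert, area-downsample,
    assign to slabs in order along ``s`` (slab k centre at (k-0.5)/n)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if len(source_images) < 1:
        raise ValueError("need at least one source image")
    for src in source_images:
        if src.shape[0] < 64 or src.shape[1] < 64:
            raise ValueError("source images must be at least 64x64")

    sel = np.floor(np.arange(n_slices) * len(source_images) / n_slices).astype(int)
    phantoms = []
    for k, si in enumerate(sel):
        src = np.asarray(source_images[si], dtype=float)
        body = src < bg_threshold
        inv = invert_intensities(src, body)
        down = np.clip(resample_area(inv, (64, 64)), 0.0, 1.0)
        phantoms.append(
            SlicePhantom(
                intensities=down,
                slice_index=k + 1,
                s_center=(k + 0.5) / n_slices,
                in_plane_resolution=in_plane_resolution,
            )
        )
    return phantoms


def generate_phantom_sources(
    rng: np.random.Generator,
    n_slices: int = 50,
    size: int = 128,
    source_resolution: float = 0.8,
    max_half_width: float = 40.0,
) -> list[np.ndarray]:
    """Synthetic TEM-like cross sections: bright background, dark tissue.

    A smooth 3D random field provides internal anatomy that varies
    continuously from slice to slice (as a real serial-section stack does),
    with a darker rim emulating the cuticle.  Intensities are kept below the
    background level so background removal by thresholding is exact.
    """
    field3 = gaussian_filter(rng.normal(size=(n_slices, size, size)),
                             sigma=(1.0, 5.0, 5.0))
    field3 = (field3 - field3.min()) / (field3.max() - field3.min() + 1e-12)

    yy, xx = np.mgrid[0:size, 0:size]
    cc = (size - 1) / 2.0
    dist = np.hypot(yy - cc, xx - cc) * source_resolution  # um from centre

    s_centers = (np.arange(n_slices) + 0.5) / n_slices
    radii = default_width_profile(s_centers, max_half_width)
    sources = []
    for k in range(n_slices):
        r = radii[k]
        body = dist <= r
        img = np.ones((size, size))
        tissue = 0.15 + 0.60 * field3[k]
        rim = (dist >= 0.82 * r) & body
        tissue = np.where(rim, tissue - 0.25, tissue)
        img[body] = np.clip(tissue[body], 0.02, 0.90)
        # partial-volume softness: real cross sections have no binary edges
        img = gaussian_filter(img, sigma=1.2)
        sources.append(img)
    return sources


def slice_worm(pose: CenterlinePose, n_slices: int = 50) -> list[SliceGeometry]:
    """Cut the body into ``n_slices`` slabs perpendicular to the centerline.

    Slab k (1-based) is centred at s = (k - 0.5) / n and is
    ``body_length / n`` thick; for the default 1.2 mm worm and 50 slabs
    that is a 24 um slice thickness.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    thickness = pose.length / n_slices
    out = []
    for k in range(n_slices):
        s = (k + 0.5) / n_slices
        t = pose.tangent_at(s)
        normal = np.array([-t[1], t[0]])
        out.append(
            SliceGeometry(center=pose.point_at(s), tangent=t, normal=normal,
                          s_center=s, thickness=thickness)
        )
    return out


# --------------------------------------------------------------------------
# dataset assembly and I/O
# --------------------------------------------------------------------------

def _self_clearance(pose: CenterlinePose, min_arc_sep: float = 250.0) -> float:
    """Smallest distance between centerline points more than
    ``min_arc_sep`` apart in arc length (large when the body is open)."""
    pts = pose.points
    arcs = pose.arc_lengths()
    tree = cKDTree(pts)
    best = np.inf
    pairs = tree.query_pairs(r=150.0, output_type="ndarray")
    if len(pairs):
        sep = np.abs(arcs[pairs[:, 0]] - arcs[pairs[:, 1]])
        far = sep > min_arc_sep
        if far.any():
            d = np.linalg.norm(pts[pairs[far, 0]] - pts[pairs[far, 1]], axis=1)
            best = float(d.min())
    return best


def generate_dataset(
    kin: WormKinematics,
    pixel_size: float = 3.0,
    noise_std: float = 0.02,
    n_slices: int = 50,
    n_centerline_points: int = 200,
) -> VideoDataset:
    """Full reproducible recording: frames, poses and phantom library.

    The field of view is sized from the ground-truth trajectory (padded by
    the body width plus a margin) so the worm never leaves the frame; the
    default 3 um/px optics make the 1.2 mm worm span ~400 raw pixels.

    Trajectories in which the worm curls onto itself (body segments
    approaching within about one body width) are rejected and redrawn from
    a derived seed: the recordings this generator emulates show openly
    crawling worms in a confined dish, and a self-occluding posture has no
    single-centerline ground truth to train or score against.
    """
    for attempt in range(20):
        ss = np.random.SeedSequence((kin.seed, attempt))
        rng_motion, rng_render, rng_phantom = [np.random.default_rng(s)
                                               for s in ss.spawn(3)]
        trace = make_trace(kin, rng_motion)
        poses = [generate_centerline(kin, k, trace, n_centerline_points)
                 for k in range(kin.n_frames)]
        clearance = min(_self_clearance(p) for p in poses)
        if clearance >= 2.4 * kin.max_half_width:
            break
    else:
        raise RuntimeError("could not draw a non-self-occluding trajectory")

    allpts = np.concatenate([p.points for p in poses])
    margin = kin.max_half_width + 12 * pixel_size
    lo = allpts.min(axis=0) - margin
    hi = allpts.max(axis=0) + margin
    W = int(math.ceil((hi[0] - lo[0]) / pixel_size / 9.0) * 9)
    H = int(math.ceil((hi[1] - lo[1]) / pixel_size / 9.0) * 9)
    origin = (float(lo[0]), float(lo[1]))

    background = make_background((H, W), rng_render)
    frames = [
        render_frame(p, pixel_size, (H, W), background, origin,
                     noise_std=noise_std, rng=rng_render)
        for p in poses
    ]

    sources = generate_phantom_sources(rng_phantom, n_slices=n_slices,
                                       max_half_width=kin.max_half_width)
    phantoms = build_slice_phantoms(sources, n_slices=n_slices)
    return VideoDataset(frames=frames, poses=poses, phantoms=phantoms,
                        kinematics=kin)


def save_dataset(dataset: VideoDataset, out_dir: str | Path) -> None:
    """Write frames/ (16-bit PNG), poses.csv, phantoms/ and kinematics.yaml."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "phantoms").mkdir(parents=True, exist_ok=True)

    for k, fr in enumerate(dataset.frames):
        arr = np.round(fr.pixels * 65535.0).astype(np.uint16)
        iio.imwrite(out / "frames" / f"frame_{k:04d}.png", arr)

    rows = []
    for k, pose in enumerate(dataset.poses):
        for i, (pt, w) in enumerate(zip(pose.points, pose.width_profile)):
            rows.append((k, i, pt[0], pt[1], w))
    pd.DataFrame(rows, columns=["frame", "point_index", "x_um", "y_um",
                                "halfwidth_um"]).to_csv(
        out / "poses.csv", index=False)

    for ph in dataset.phantoms:
        arr = np.round(ph.intensities * 65535.0).astype(np.uint16)
        iio.imwrite(out / "phantoms" / f"slice_{ph.slice_index:02d}.png", arr)

    meta = {
        "kinematics": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in vars(dataset.kinematics).items()},
        "pixel_size": dataset.pixel_size,
        "origin_um": list(dataset.origin_um),
        "n_frames": dataset.n_frames,
        "n_phantoms": len(dataset.phantoms),
        "phantom_resolution": dataset.phantoms[0].in_plane_resolution,
    }
    with open(out / "kinematics.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_dataset(in_dir: str | Path) -> VideoDataset:
    """Inverse of :func:`save_dataset` (16-bit quantization aside)."""
    src = Path(in_dir)
    with open(src / "kinematics.yaml") as fh:
        meta = yaml.safe_load(fh)
    kin = WormKinematics(**meta["kinematics"])
    pixel_size = float(meta["pixel_size"])
    origin = tuple(meta["origin_um"])

    frames = []
    for k in range(int(meta["n_frames"])):
        arr = iio.imread(src / "frames" / f"frame_{k:04d}.png")
        frames.append(FrameImage(arr.astype(np.float32) / 65535.0,
                                 pixel_size, origin))

    df = pd.read_csv(src / "poses.csv")
    poses = []
    for k, grp in df.groupby("frame"):
        grp = grp.sort_values("point_index")
        poses.append(CenterlinePose(
            timestamp=int(k),
            points=grp[["x_um", "y_um"]].to_numpy(),
            width_profile=grp["halfwidth_um"].to_numpy()))

    res = float(meta.get("phantom_resolution", 1.6))
    n_ph = int(meta["n_phantoms"])
    phantoms = []
    for k in range(1, n_ph + 1):
        arr = iio.imread(src / "phantoms" / f"slice_{k:02d}.png")
        phantoms.append(SlicePhantom(arr.astype(float) / 65535.0, k,
                                     (k - 0.5) / n_ph, res))
    return VideoDataset(frames=frames, poses=poses, phantoms=phantoms,
                        kinematics=kin)
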