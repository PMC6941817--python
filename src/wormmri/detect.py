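"""Worm detection and center-line coordinate system.

Per-frame pipeline: 9x9 block-mean downsampling -> temporal-median
background subtraction -> Otsu segmentation (largest component, holes
filled) -> smoothed centre of gravity -> head assignment from accumulated
difference images -> skeletonization into an ordered head->tail path with a
normalized arc-length coordinate s in [0, 1] -> centerline velocity.

The velocity is expressed in normalized s-units per frame (worm speed
divided by skeleton length), the unit the coordinate predictor
``s_c = s - v * dk`` expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing, binary_fill_holes
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize as _thin

from .synthgen import FrameImage, VideoDataset

__all__ = [
    "DOWNSAMPLE_FACTOR",
    "PreprocessedFrame",
    "BackgroundModel",
    "WormMask",
    "Skeleton",
    "TrackState",
    "TrackResult",
    "WormAbsentError",
    "SkeletonError",
    "preprocess",
    "estimate_background",
    "segment",
    "compute_cog",
    "detect_head",
    "skeletonize",
    "locate_poi",
    "estimate_velocity",
    "extend_on_weight",
    "refine_centerline",
    "track_video",
]

DOWNSAMPLE_FACTOR = 9


class WormAbsentError(RuntimeError):
    """No sufficiently large foreground component in the frame."""


class SkeletonError(RuntimeError):
    """Thinning produced an irreducibly branched skeleton."""


@dataclass
class PreprocessedFrame:
    pixels: np.ndarray
    index: int = 0
    scale_factor: int = DOWNSAMPLE_FACTOR


@dataclass
class BackgroundModel:
    pixels: np.ndarray


@dataclass
class WormMask:
    pixels: np.ndarray   # boolean
    connected: bool = True

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class Skeleton:
    """Ordered 1-px centerline path, head first.

    ``path`` holds fractional (row, col) node positions in downsampled
    pixels (lightly smoothed to reduce lattice quantization), ``arclen``
    the cumulative arc length and ``s_of_node`` the normalized coordinate.
    """

    path: np.ndarray        # (n, 2) float (row, col)
    arclen: np.ndarray      # (n,) cumulative, arclen[0] = 0
    s_of_node: np.ndarray   # (n,) in [0, 1], strictly increasing

    @property
    def length(self) -> float:
        return float(self.arclen[-1])

    @property
    def head(self) -> np.ndarray:
        return self.path[0]

    @property
    def tail(self) -> np.ndarray:
        return self.path[-1]

    def point_at(self, s: float) -> np.ndarray:
        return locate_poi(self, s)

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent (head -> tail direction) at coordinate s."""
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"s={s} outside [0, 1]")
        target = s * self.length
        i = int(np.clip(np.searchsorted(self.arclen, target) - 1,
                        0, len(self.path) - 2))
        d = self.path[i + 1] - self.path[i]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 1.0])


@dataclass
class TrackState:
    """Evolving per-video tracker state (COG history is smoothed)."""

    cog_history: list = field(default_factory=list)
    head: np.ndarray | None = None
    v: float = 0.0
    frame: int = -1


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def preprocess(raw: FrameImage | np.ndarray, index: int = 0) -> PreprocessedFrame:
    """Block-mean downsampling by 9 along each axis (edge blocks partial)."""
    pix = raw.pixels if isinstance(raw, FrameImage) else np.asarray(raw)
    if pix.ndim != 2 or pix.shape[0] < DOWNSAMPLE_FACTOR or pix.shape[1] < DOWNSAMPLE_FACTOR:
        raise ValueError("frame must be 2D and at least 9x9")
    f = DOWNSAMPLE_FACTOR
    H, W = pix.shape
    ri = np.arange(0, H, f)
    ci = np.arange(0, W, f)
    sums = np.add.reduceat(np.add.reduceat(pix.astype(float), ri, axis=0),
                           ci, axis=1)
    rh = np.minimum(ri + f, H) - ri
    cw = np.minimum(ci + f, W) - ci
    out = sums / np.outer(rh, cw)
    return PreprocessedFrame(pixels=out, index=index)


def estimate_background(frames: list[PreprocessedFrame]) -> BackgroundModel:
    """Per-pixel temporal median; robust as long as the worm covers any one
    pixel in fewer than half the frames."""
    if len(frames) < 3:
        raise ValueError("background estimation needs at least 3 frames")
    stack = np.stack([f.pixels for f in frames])
    return BackgroundModel(pixels=np.median(stack, axis=0))


def segment(frame: PreprocessedFrame, bg: BackgroundModel,
            min_area: int = 15) -> WormMask:
    """Threshold the background difference (Otsu), keep the largest
    connected component, fill holes.

    The worm is darker than the bright field, so the signed difference
    ``background - frame`` is used: residual dark smudges in the background
    model (left where the worm lingered) produce only negative differences
    and cannot create ghost components.  Raises :class:`WormAbsentError`
    when the largest component is below ``min_area`` pixels or the
    difference image is flat.
    """
    if frame.pixels.shape != bg.pixels.shape:
        raise ValueError("frame/background shape mismatch")
    diff = np.clip(bg.pixels - frame.pixels, 0.0, None)
    if diff.max() - diff.min() < 1e-6:
        raise WormAbsentError("difference image is flat")
    th = threshold_otsu(diff)
    raw = binary_closing(diff > th, structure=np.ones((3, 3)))
    lab, n = label(raw, connectivity=2, return_num=True)
    if n == 0:
        raise WormAbsentError("no foreground component")
    sizes = np.bincount(lab.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise WormAbsentError(f"largest component {sizes[best - 1]} px < {min_area}")
    mask = binary_fill_holes(lab == best)
    return WormMask(pixels=mask, connected=True)


def compute_cog(mask: WormMask, prev_cog: np.ndarray | None = None,
                alpha: float = 0.5) -> np.ndarray:
    """Smoothed centre of gravity of the foreground, (row, col).

    First-order low pass: ``alpha * raw + (1 - alpha) * previous``; the
    first frame passes through unfiltered.
    """
    if mask.area == 0:
        raise ValueError("empty mask")
    rc = np.argwhere(mask.pixels).mean(axis=0)
    if prev_cog is None:
        return rc
    return alpha * rc + (1.0 - alpha) * np.asarray(prev_cog, dtype=float)


def _trace_longest_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic through the morphological skeleton of ``mask``,
    as an ordered (n, 2) integer pixel chain (orientation arbitrary)."""
    skel = _thin(mask)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise SkeletonError("skeleton has fewer than 2 pixels")
    index = -np.ones(mask.shape, dtype=int)
    index[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    rows, cols, data = [], [], []
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    H, W = mask.shape
    for i, (r, c) in enumerate(coords):
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and index[rr, cc] >= 0:
                rows.append(i)
                cols.append(index[rr, cc])
                data.append(float(np.hypot(dr, dc)))
    n = len(coords)
    graph = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def farthest(src: int):
        d = dijkstra(graph, indices=src)
        d[~np.isfinite(d)] = -1.0
        return int(np.argmax(d))

    a = farthest(0)
    dist, pred = dijkstra(graph, indices=a, return_predecessors=True)
    dist[~np.isfinite(dist)] = -1.0
    b = int(np.argmax(dist))
    chain = [b]
    while chain[-1] != a:
        p = pred[chain[-1]]
        if p < 0:
            raise SkeletonError("disconnected skeleton")
        chain.append(int(p))
    path = coords[np.array(chain[::-1])]
    if len(path) < 0.5 * n:
        raise SkeletonError(
            f"longest path covers only {len(path)}/{n} skeleton pixels")
    return path


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both path ends along their local tangent until they leave the
    mask, recovering tip length lost to morphological thinning."""
    H, W = mask.shape

    def extend(end: np.ndarray, inward: np.ndarray) -> list[np.ndarray]:
        d = end - inward
        n = np.linalg.norm(d)
        if n == 0:
            return []
        d = d / n
        out, p = [], end.astype(float)
        for _ in range(40):
            p = p + 0.5 * d
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
                break
            out.append(p.copy())
        return out

    k = min(3, len(path) - 1)
    head_ext = extend(path[0].astype(float), path[k].astype(float))
    tail_ext = extend(path[-1].astype(float), path[-1 - k].astype(float))
    parts = [np.array(head_ext[::-1]).reshape(-1, 2), path.astype(float),
             np.array(tail_ext).reshape(-1, 2)]
    return np.concatenate([p for p in parts if len(p)], axis=0)


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of node coordinates, endpoints pinned."""
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    sm = np.column_stack([
        np.convolve(path[:, 0], kernel, mode="same"),
        np.convolve(path[:, 1], kernel, mode="same"),
    ])
    h = window // 2
    sm[:h] = path[:h]
    sm[-h:] = path[-h:]
    return sm


def extend_on_weight(skel: Skeleton, weight: np.ndarray,
                     rel_threshold: float = 0.25,
                     max_px: float = 6.0) -> Skeleton:
    """Extend both skeleton ends along their tangents through the grey
    difference image.

    Binary thinning stops where Otsu's threshold cuts the faint tapered
    tips (the whip-like tail especially), shortening the skeleton and
    destabilising the normalized coordinate.  Walking outward while the
    difference signal stays above ``rel_threshold`` of its value at the
    endpoint recovers the sub-threshold tips.
    """
    from scipy.ndimage import map_coordinates

    def sample(p: np.ndarray) -> float:
        return float(map_coordinates(weight, [[p[0]], [p[1]]], order=1,
                                     mode="constant", cval=0.0)[0])

    def extend(end: np.ndarray, inward: np.ndarray) -> list[np.ndarray]:
        d = end - inward
        nrm = np.linalg.norm(d)
        if nrm == 0:
            return []
        d = d / nrm
        floor = rel_threshold * max(sample(end), 1e-6)
        out, p = [], end.copy()
        for _ in range(int(max_px / 0.5)):
            q = p + 0.5 * d
            if sample(q) < floor:
                break
            out.append(q)
            p = q
        return out

    path = skel.path
    k = min(3, len(path) - 1)
    head_ext = extend(path[0], path[k])
    tail_ext = extend(path[-1], path[-1 - k])
    parts = [np.array(head_ext[::-1]).reshape(-1, 2), path,
             np.array(tail_ext).reshape(-1, 2)]
    new_path = np.concatenate([p for p in parts if len(p)], axis=0)
    seg = np.linalg.norm(np.diff(new_path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return Skeleton(path=new_path, arclen=arclen,
                    s_of_node=arclen / arclen[-1])


def refine_centerline(skel: Skeleton, weight: np.ndarray,
                      halfwin: float = 2.0) -> Skeleton:
    """Sub-pixel transverse refinement of a skeleton against an image.

    Each node is moved along its local normal to the intensity-weighted
    centroid of ``weight`` (e.g. the background-minus-frame difference,
    large inside the worm) sampled within ``halfwin`` pixels, removing the
    half-pixel lattice quantization of morphological thinning.
    """
    from scipy.ndimage import map_coordinates

    path = skel.path.copy()
    n = len(path)
    if n < 3:
        return skel
    tang = np.gradient(path, axis=0)
    norms = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    mag = np.linalg.norm(norms, axis=1, keepdims=True)
    mag[mag == 0] = 1.0
    norms = norms / mag
    offsets = np.linspace(-halfwin, halfwin, 9)
    # sample weight at node + o * normal for all offsets
    coords = path[None, :, :] + offsets[:, None, None] * norms[None, :, :]
    vals = map_coordinates(weight, [coords[..., 0].ravel(),
                                    coords[..., 1].ravel()],
                           order=1, mode="nearest").reshape(len(offsets), n)
    vals = np.clip(vals, 0.0, None) ** 2
    tot = vals.sum(axis=0)
    good = tot > 1e-9
    shift = np.zeros(n)
    shift[good] = (vals[:, good] * offsets[:, None]).sum(axis=0) / tot[good]
    shift = np.clip(shift, -halfwin, halfwin)
    new_path = path + shift[:, None] * norms
    new_path = _smooth_path(new_path, window=3)
    seg = np.linalg.norm(np.diff(new_path, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    new_path = new_path[keep]
    seg = np.linalg.norm(np.diff(new_path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return Skeleton(path=new_path, arclen=arclen,
                    s_of_node=arclen / arclen[-1])


def detect_head(window: list[PreprocessedFrame], mask: WormMask,
                prev_head: np.ndarray | None = None,
                radius: float = 7.0, margin: float = 0.10) -> np.ndarray:
    """Head = skeleton endpoint with the larger accumulated difference-image
    mass in its neighbourhood (the head moves most).

    The scores sum squared frame-to-frame differences over the window (up
    to the last 10 frames).  When the two endpoint scores differ by less than
    ``margin`` the assignment is low-confidence and falls back to the
    endpoint nearest the previous head (a motionless worm keeps its head).
    """
    if len(window) < 2 and prev_head is None:
        raise ValueError("need at least 2 frames or a previous head")
    path = _trace_longest_path(mask.pixels)
    ends = np.array([path[0], path[-1]], dtype=float)

    acc = np.zeros_like(mask.pixels, dtype=float)
    for a, b in zip(window[:-1], window[1:]):
        # squared differences (motion energy): weights the head's fast
        # full-contrast flicker over slow broad body sweeps
        acc += np.square(b.pixels - a.pixels)

    H, W = acc.shape
    scores = []
    for e in ends:
        r0 = max(int(e[0] - radius), 0)
        r1 = min(int(e[0] + radius) + 1, H)
        c0 = max(int(e[1] - radius), 0)
        c1 = min(int(e[1] + radius) + 1, W)
        scores.append(float(acc[r0:r1, c0:c1].sum()))
    scores = np.asarray(scores)

    top = scores.max()
    if top <= 0 or abs(scores[0] - scores[1]) < margin * max(top, 1e-12):
        if prev_head is not None:
            d = np.linalg.norm(ends - np.asarray(prev_head), axis=1)
            return ends[int(np.argmin(d))]
        return ends[int(np.argmax(scores))]
    pick = int(np.argmax(scores))
    if prev_head is not None:
        # identity persistence: within one frame interval the head cannot
        # jump to the far end of the body, so a flip of the score-preferred
        # endpoint is accepted only on an overwhelming (>2x) margin
        d = np.linalg.norm(ends - np.asarray(prev_head), axis=1)
        seglen = np.linalg.norm(ends[0] - ends[1])
        if (d[pick] > 0.5 * seglen > d[1 - pick]
                and scores[pick] < 2.0 * scores[1 - pick]):
            return ends[1 - pick]
    return ends[pick]


def skeletonize(mask: WormMask, head: np.ndarray) -> Skeleton:
    """Thin the mask to an ordered centerline starting at the endpoint
    nearest ``head``, with s = cumulative arc length / total length."""
    path = _trace_longest_path(mask.pixels)
    path = _extend_to_boundary(path, mask.pixels)
    head = np.asarray(head, dtype=float)
    if np.linalg.norm(path[-1] - head) < np.linalg.norm(path[0] - head):
        path = path[::-1].copy()
    path = _smooth_path(path)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    path = path[keep]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] <= 0:
        raise SkeletonError("degenerate skeleton")
    return Skeleton(path=path, arclen=arclen, s_of_node=arclen / arclen[-1])


def locate_poi(skel: Skeleton, s: float) -> np.ndarray:
    """Point at normalized coordinate ``s`` by linear interpolation along
    the skeleton path."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s={s} outside [0, 1]")
    target = s * skel.length
    r = np.interp(target, skel.arclen, skel.path[:, 0])
    c = np.interp(target, skel.arclen, skel.path[:, 1])
    return np.array([r, c])


def estimate_velocity(track: TrackState, skel: Skeleton,
                      window: int = 5) -> float:
    """Worm speed in normalized s-units per frame.

    Per-frame smoothed-COG displacements over the last ``window`` frames
    are projected on the local travel direction (the net displacement
    axis, which suppresses lateral undulation noise), combined by their
    median, signed by the head-ward chord of the current skeleton, and
    normalized by the skeleton length.  Negative (backward) values are
    clamped to 0.
    """
    hist = track.cog_history
    if len(hist) < 2:
        return 0.0
    m = min(window, len(hist) - 1)
    chord = skel.head - skel.tail
    n = np.linalg.norm(chord)
    if n == 0 or skel.length == 0:
        return 0.0
    recent = np.asarray(hist[-(m + 1):], dtype=float)
    steps = np.diff(recent, axis=0)
    net = recent[-1] - recent[0]
    nn = np.linalg.norm(net)
    if nn == 0:
        return 0.0
    # travel axis = direction of net displacement (unbiased by body bend);
    # the head-ward chord only decides forward vs backward; median over the
    # window is robust to single-frame segmentation glitches
    axis = net / nn
    sign = 1.0 if float(net @ (chord / n)) >= 0 else -1.0
    v = sign * float(np.median(steps @ axis)) / skel.length
    return max(0.0, v)


# --------------------------------------------------------------------------
# whole-video tracking
# --------------------------------------------------------------------------

@dataclass
class TrackResult:
    """Per-frame tracking output for one video, in downsampled pixels,
    with the transform back to world micrometres."""

    skeletons: list            # Skeleton | None per frame
    cogs: list                 # smoothed (row, col) | None
    heads: list                # (row, col) | None
    velocities: list           # float, s-units / frame
    pixel_size: float          # raw um / px
    origin_um: tuple[float, float]
    scale_factor: int = DOWNSAMPLE_FACTOR

    @property
    def n_frames(self) -> int:
        return len(self.skeletons)

    def to_world(self, rc: np.ndarray) -> np.ndarray:
        """Downsampled (row, col) -> world (x, y) um (block centres)."""
        rc = np.asarray(rc, dtype=float)
        f, p = self.scale_factor, self.pixel_size
        x = self.origin_um[0] + (rc[..., 1] * f + f / 2.0) * p
        y = self.origin_um[1] + (rc[..., 0] * f + f / 2.0) * p
        return np.stack([x, y], axis=-1)

    @property
    def world_scale(self) -> float:
        """um per downsampled pixel."""
        return self.pixel_size * self.scale_factor


def track_video(dataset: VideoDataset, alpha: float = 0.5,
                head_window: int = 10, min_area: int = 15) -> TrackResult:
    """Run the full detection chain over every frame of a video.

    The head of the very first frames is assigned from a forward-looking
    difference window (offline warm-up); thereafter the causal last-10-frame
    window of the online method is used.
    """
    pfs = [preprocess(fr, k) for k, fr in enumerate(dataset.frames)]
    bg = estimate_background(pfs)

    skels, cogs, heads, vels = [], [], [], []
    state = TrackState()
    warm = pfs[: min(head_window, len(pfs))]

    # initial head side from the direction of travel over a ~2 s warm-up
    # (worms crawl head-first); with negligible net motion, fall back to
    # the difference-image score of the first usable frame
    first_path = None
    first_cog = None
    last_cog = None
    for k in range(min(3 * head_window, len(pfs))):
        try:
            m0 = segment(pfs[k], bg, min_area=min_area)
        except WormAbsentError:
            continue
        cog0 = np.argwhere(m0.pixels).mean(axis=0)
        if first_path is None:
            try:
                first_path = _trace_longest_path(m0.pixels)
            except SkeletonError:
                continue
            first_cog = cog0
        last_cog = cog0
    if first_path is not None and last_cog is not None:
        ends = np.array([first_path[0], first_path[-1]], dtype=float)
        net = last_cog - first_cog
        if np.linalg.norm(net) > 2.0:
            along = (ends - first_cog) @ net
            state.head = ends[int(np.argmax(along))]
        else:
            try:
                m0 = segment(pfs[0], bg, min_area=min_area)
                state.head = detect_head(warm, m0, prev_head=None)
            except (WormAbsentError, SkeletonError, ValueError):
                pass
    for k, pf in enumerate(pfs):
        try:
            mask = segment(pf, bg, min_area=min_area)
        except WormAbsentError:
            skels.append(None)
            cogs.append(None)
            heads.append(None)
            vels.append(0.0)
            continue
        prev = state.cog_history[-1] if state.cog_history else None
        cog = compute_cog(mask, prev, alpha=alpha)
        state.cog_history.append(cog)

        window = warm if k < head_window else pfs[k - head_window + 1: k + 1]
        head = detect_head(window, mask, prev_head=state.head)
        skel = skeletonize(mask, head)
        diffimg = bg.pixels - pf.pixels
        skel = extend_on_weight(skel, diffimg)
        skel = refine_centerline(skel, diffimg)

        # temporal length gate: when the nose folds onto the body the mask
        # merges and the medial path shortcuts or grows; such frames are
        # replaced by the last consistent skeleton (coasting)
        good_lens = [sk.length for sk in skels[-10:] if sk is not None]
        if good_lens:
            med = float(np.median(good_lens))
            if abs(skel.length - med) > 0.2 * med and skels[-1] is not None:
                skel = skels[-1]
        state.head = skel.head
        state.frame = k
        v = estimate_velocity(state, skel)
        state.v = v

        skels.append(skel)
        cogs.append(cog)
        heads.append(skel.head)
        vels.append(v)

    return TrackResult(skeletons=skels, cogs=cogs, heads=heads,
                       velocities=vels, pixel_size=dataset.pixel_size,
                       origin_um=dataset.origin_um)
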