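"""Shared fixtures: one small tracked recording reused across module tests.

The small recording (5 s, 60 frames) exercises the full pipeline cheaply;
the full-length study videos live in the acceptance suite.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormmri import detect, synthgen

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_kin() -> synthgen.WormKinematics:
    return synthgen.WormKinematics(seed=123, duration=6.0)


@pytest.fixture(scope="session")
def small_dataset(small_kin) -> synthgen.VideoDataset:
    return synthgen.generate_dataset(small_kin)


@pytest.fixture(scope="session")
def small_track(small_dataset) -> detect.TrackResult:
    return detect.track_video(small_dataset)


@pytest.fixture(scope="session")
def default_dataset() -> synthgen.VideoDataset:
    """One full-length (10 s) recording at the study conditions."""
    return synthgen.generate_dataset(synthgen.WormKinematics(seed=11))


@pytest.fixture(scope="session")
def default_track(default_dataset) -> detect.TrackResult:
    return detect.track_video(default_dataset)


def rasterize_pose_mask(dataset, frame, shape):
    """Ground-truth worm mask at downsampled-pixel resolution."""
    from scipy.spatial import cKDTree

    pose = dataset.poses[frame]
    f = detect.DOWNSAMPLE_FACTOR
    p = dataset.pixel_size
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    cx = dataset.origin_um[0] + (cols * f + f / 2) * p
    cy = dataset.origin_um[1] + (rows * f + f / 2) * p
    arcs = pose.arc_lengths()
    t = np.arange(0, arcs[-1], 2.0)
    dx = np.interp(t, arcs, pose.points[:, 0])
    dy = np.interp(t, arcs, pose.points[:, 1])
    dw = np.interp(t, arcs, pose.width_profile)
    dist, idx = cKDTree(np.stack([dx, dy], 1)).query(
        np.stack([cx.ravel(), cy.ravel()], 1))
    return (dist <= dw[idx]).reshape(H, W)
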