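"""Detection-chain tests: preprocessing, background, segmentation, head,
skeleton coordinate system and velocity."""

import numpy as np
import pytest

from wormmri import detect
from wormmri.detect import (BackgroundModel, PreprocessedFrame, Skeleton,
                            TrackState, WormAbsentError, WormMask,
                            compute_cog, detect_head, estimate_background,
                            estimate_velocity, locate_poi, preprocess,
                            segment, skeletonize)
from .conftest import rasterize_pose_mask


def make_skeleton(points):
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return Skeleton(path=pts, arclen=arclen, s_of_node=arclen / arclen[-1])


class TestPreprocess:
    def test_size_arithmetic(self):
        out = preprocess(np.zeros((900, 900)))
        assert out.pixels.shape == (100, 100)
        out = preprocess(np.zeros((91, 100)))
        assert out.pixels.shape == (11, 12)  # ceil(91/9), ceil(100/9)

    def test_constant_preserved(self):
        out = preprocess(np.full((45, 54), 0.37))
        np.testing.assert_allclose(out.pixels, 0.37, atol=1e-12)

    def test_uniform_blocks_recovered_exactly(self):
        rng = np.random.default_rng(1)
        blocks = rng.uniform(size=(5, 7))
        img = np.kron(blocks, np.ones((9, 9)))
        out = preprocess(img)
        np.testing.assert_allclose(out.pixels, blocks, atol=1e-12)

    def test_rejects_tiny_frames(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((5, 5)))


class TestBackground:
    def test_identical_frames_give_that_frame(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(20, 20))
        frames = [PreprocessedFrame(img.copy(), k) for k in range(5)]
        bg = estimate_background(frames)
        np.testing.assert_array_equal(bg.pixels, img)

    def test_transient_dark_worm_removed_exactly(self):
        # oracle: per-pixel median over frames where the worm covers any
        # pixel in fewer than half of them
        rng = np.random.default_rng(2)
        truth = rng.uniform(0.6, 0.9, size=(15, 15))
        frames = []
        for k in range(11):
            img = truth.copy()
            img[:, k] = 0.1       # dark column sweeping through
            frames.append(PreprocessedFrame(img, k))
        bg = estimate_background(frames)
        np.testing.assert_allclose(bg.pixels, truth, atol=1e-12)

    def test_median_concentrates_under_noise(self):
        rng = np.random.default_rng(3)
        truth = np.full((30, 30), 0.7)
        frames = [PreprocessedFrame(truth + rng.normal(0, 0.05, truth.shape), k)
                  for k in range(60)]
        bg = estimate_background(frames)
        # median of n noisy samples concentrates ~ sigma * sqrt(pi/(2n))
        assert np.abs(bg.pixels - truth).mean() < 3 * 0.05 / np.sqrt(60)

    def test_needs_three_frames(self):
        with pytest.raises(ValueError):
            estimate_background([PreprocessedFrame(np.zeros((9, 9)), 0)] * 2)


def _tube_frame(shape=(40, 60), row=20, c0=10, c1=50, halfwidth=2,
                level=0.2, bg=0.8):
    img = np.full(shape, bg)
    img[row - halfwidth: row + halfwidth + 1, c0:c1 + 1] = level
    return img


class TestSegment:
    def test_worm_free_frame_signals_absent(self):
        bg = BackgroundModel(np.full((30, 30), 0.8))
        frame = PreprocessedFrame(np.full((30, 30), 0.8))
        with pytest.raises(WormAbsentError):
            segment(frame, bg)

    def test_largest_component_wins_over_speck(self):
        bg = BackgroundModel(np.full((40, 60), 0.8))
        img = _tube_frame()
        img[5, 5] = 0.2   # isolated dark speck
        mask = segment(PreprocessedFrame(img), bg)
        assert not mask.pixels[5, 5]
        assert mask.pixels[20, 30]

    def test_mask_iou_against_ground_truth(self, default_dataset):
        pfs = [preprocess(fr, k) for k, fr in
               enumerate(default_dataset.frames)]
        bg = estimate_background(pfs)
        ious = []
        for k in range(0, default_dataset.n_frames, 8):
            mask = segment(pfs[k], bg)
            gt = rasterize_pose_mask(default_dataset, k, mask.pixels.shape)
            inter = (gt & mask.pixels).sum()
            union = (gt | mask.pixels).sum()
            ious.append(inter / union)
        assert np.mean(ious) >= 0.7


class TestCog:
    def test_single_pixel_no_history(self):
        m = np.zeros((10, 10), bool)
        m[3, 7] = True
        np.testing.assert_allclose(compute_cog(WormMask(m)), [3.0, 7.0])

    def test_constant_mask_is_filter_fixed_point(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 4:8] = True
        cog = compute_cog(WormMask(m))
        for _ in range(5):
            nxt = compute_cog(WormMask(m), cog, alpha=0.5)
            np.testing.assert_allclose(nxt, cog)
            cog = nxt

    def test_alpha_one_passes_raw_through(self):
        m = np.zeros((10, 10), bool)
        m[1, 1] = True
        out = compute_cog(WormMask(m), prev_cog=np.array([9.0, 9.0]),
                          alpha=1.0)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_cog(WormMask(np.zeros((5, 5), bool)))


class TestHead:
    def test_motionless_worm_falls_back_to_previous_head(self):
        img = _tube_frame()
        frames = [PreprocessedFrame(img.copy(), k) for k in range(10)]
        mask = WormMask(img < 0.5)
        prev = np.array([20.0, 10.0])
        head = detect_head(frames, mask, prev_head=prev)
        assert np.linalg.norm(head - prev) < 3.0

    def test_flickering_end_wins(self):
        # one end of the tube toggles between frames: that end is the head
        frames = []
        for k in range(10):
            img = _tube_frame()
            if k % 2:
                img[16:25, 46:52] = 0.2   # extra dark blob at the right end
            frames.append(PreprocessedFrame(img, k))
        mask = WormMask(_tube_frame() < 0.5)
        head = detect_head(frames, mask)
        assert head[1] > 40   # right end chosen

    def test_head_assignment_accuracy_on_default_video(self, default_dataset,
                                                       default_track):
        tr = default_track
        errs = [np.linalg.norm(tr.to_world(tr.skeletons[k].head)
                               - default_dataset.poses[k].points[0])
                for k in range(default_dataset.n_frames)]
        assert np.mean(np.asarray(errs) < 150.0) >= 0.9


class TestSkeleton:
    def test_straight_tube_orientation_and_length(self):
        img = _tube_frame(shape=(40, 130), row=20, c0=10, c1=110)
        mask = WormMask(img < 0.5)
        skel = skeletonize(mask, head=np.array([20.0, 10.0]))
        assert skel.path[0][1] < skel.path[-1][1]      # left to right
        assert skel.s_of_node[0] == 0.0
        assert skel.s_of_node[-1] == 1.0
        assert skel.length == pytest.approx(100.0, abs=2.0)
        # reversing the head flips the orientation
        rev = skeletonize(mask, head=np.array([20.0, 110.0]))
        assert rev.path[0][1] > rev.path[-1][1]

    def test_s_monotone_on_tracked_video(self, small_track):
        for skel in small_track.skeletons:
            if skel is None:
                continue
            assert (np.diff(skel.s_of_node) > 0).all()

    def test_length_close_to_ground_truth(self, default_dataset,
                                          default_track):
        scale = default_track.world_scale
        lens = [s.length * scale for s in default_track.skeletons
                if s is not None]
        assert np.median(lens) == pytest.approx(1200.0, rel=0.05)


class TestLocatePoi:
    def test_endpoints_and_midpoint(self):
        skel = make_skeleton([[50, 10], [50, 60], [50, 110]])
        np.testing.assert_allclose(locate_poi(skel, 0.0), [50, 10])
        np.testing.assert_allclose(locate_poi(skel, 1.0), [50, 110])
        np.testing.assert_allclose(locate_poi(skel, 0.5), [50, 60])

    def test_out_of_range_rejected(self):
        skel = make_skeleton([[0, 0], [0, 10]])
        for s in (-0.1, 1.1):
            with pytest.raises(ValueError):
                locate_poi(skel, s)


class TestVelocity:
    def test_stationary_worm_gives_zero(self):
        skel = make_skeleton([[20, 10], [20, 60]])
        track = TrackState(cog_history=[np.array([20.0, 30.0])] * 6)
        assert estimate_velocity(track, skel) == 0.0

    def test_pure_translation_recovers_speed(self):
        # worm of length 50 px translating 0.5 px/frame toward its head
        skel = make_skeleton([[20, 60], [20, 10]])   # head at col 60
        cogs = [np.array([20.0, 30.0 + 0.5 * k]) for k in range(8)]
        track = TrackState(cog_history=cogs)
        v = estimate_velocity(track, skel)
        assert v == pytest.approx(0.5 / 50.0, rel=1e-6)

    def test_backward_motion_clamped_to_zero(self):
        skel = make_skeleton([[20, 60], [20, 10]])   # head at col 60
        cogs = [np.array([20.0, 30.0 - 0.5 * k]) for k in range(8)]
        track = TrackState(cog_history=cogs)
        assert estimate_velocity(track, skel) == 0.0

    def test_speed_recovery_on_default_video(self, default_track):
        target = 130.0 / 12.0 / 1200.0
        v = np.mean(default_track.velocities[20:])
        assert v == pytest.approx(target, rel=0.10)

    def test_doubling_speed_doubles_velocity(self):
        # linearity check with a gait-consistent speed change (a worm
        # doubles its speed by doubling its bend frequency), averaged over
        # three recordings per speed to beat single-video tracking noise
        from wormmri import synthgen

        def mean_v(speed, freq):
            vs = []
            for seed in (5, 21, 31):
                kin = synthgen.WormKinematics(
                    seed=seed, speed=speed, undulation_frequency=freq)
                tr = detect.track_video(synthgen.generate_dataset(kin))
                vs.append(np.mean(tr.velocities[20:]))
            return np.mean(vs)

        v1 = mean_v(130.0, 0.3)
        v2 = mean_v(260.0, 0.6)
        assert v2 / v1 == pytest.approx(2.0, rel=0.10)
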