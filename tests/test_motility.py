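"""Mobility analysis: moving average, MSD against brute force, MAD rule, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatmeth import motility, synthgen
from repeatmeth.motility import (
    MSDProfile,
    Trajectory,
    compute_msd,
    fit_diffusion,
    mobility_summary,
    scaled_mad_filter,
    temporal_moving_average,
    track_spots,
)
from repeatmeth.stacks import ImageStack


def brute_force_msd(coords, dt, max_k=None):
    """Independent oracle: explicit double loop over all ordered pairs."""
    n = len(coords)
    max_k = max_k or n - 1
    lags, msds, counts = [], [], []
    for k in range(1, max_k + 1):
        total, m = 0.0, 0
        for t in range(n - k):
            dx = coords[t + k][0] - coords[t][0]
            dy = coords[t + k][1] - coords[t][1]
            total += dx * dx + dy * dy
            m += 1
        if m:
            lags.append(k * dt)
            msds.append(total / m)
            counts.append(m)
    return np.array(lags), np.array(msds), np.array(counts)


def _movie(frames):
    return ImageStack(
        pixels=np.asarray(frames, dtype=float)[None],
        channel_names=("reporter",),
        pixel_size=0.1,
        frame_interval=0.1,
    )


class TestMovingAverage:
    def test_constant_movie_unchanged_but_shorter(self):
        movie = _movie(np.full((10, 4, 4), 3.0))
        out = temporal_moving_average(movie, window=5)
        assert out.n_planes == 6
        assert np.allclose(out.pixels, 3.0)

    def test_window_one_is_identity(self, rng):
        movie = _movie(rng.normal(size=(6, 4, 4)))
        out = temporal_moving_average(movie, window=1)
        assert np.array_equal(out.pixels, movie.pixels)

    def test_pixel_series_arithmetic(self):
        frames = np.array([[[v]] for v in [1.0, 2, 3, 4, 5, 6]])
        out = temporal_moving_average(_movie(frames), window=5)
        assert np.allclose(out.pixels[0, :, 0, 0], [3.0, 4.0])

    def test_invalid_window_rejected(self):
        movie = _movie(np.zeros((4, 2, 2)))
        for window in (0, 5):
            with pytest.raises(ValueError, match="window"):
                temporal_moving_average(movie, window=window)


class TestComputeMSD:
    def test_stationary_trajectory_is_zero(self):
        tr = Trajectory(id=0, frame_interval=0.1, coords=np.tile([1.0, 2.0], (8, 1)))
        profile = compute_msd(tr, mode="ensemble")
        assert np.allclose(profile.msd, 0.0)

    def test_ballistic_motion_is_quadratic(self):
        v, dt = 0.3, 0.5
        t = np.arange(20) * dt
        tr = Trajectory(id=0, frame_interval=dt, coords=np.column_stack([v * t, 0 * t]))
        profile = compute_msd(tr, mode="ensemble")
        assert np.allclose(profile.msd, v**2 * profile.lags**2)

    def test_hand_worked_example(self):
        tr = Trajectory(
            id=0, frame_interval=1.0,
            coords=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [2.0, 1.0]]),
        )
        profile = compute_msd(tr, mode="ensemble")
        assert profile.msd_at(1.0) == pytest.approx(1.0)
        assert profile.msd_at(2.0) == pytest.approx(2.0)
        assert list(profile.n_pairs) == [3, 2, 1]

    def test_matches_brute_force_oracle_on_random_trajectories(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            coords = rng.normal(size=(n, 2))
            tr = Trajectory(id=0, frame_interval=0.1, coords=coords)
            profile = compute_msd(tr, mode="ensemble")
            lags, msds, counts = brute_force_msd(coords, 0.1)
            np.testing.assert_allclose(profile.lags, lags, rtol=1e-12)
            np.testing.assert_allclose(profile.msd, msds, rtol=1e-12)
            assert np.array_equal(profile.n_pairs, counts)

    @settings(deadline=None, max_examples=25)
    @given(
        shift=st.tuples(
            st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
        ),
        angle=st.floats(0, 2 * np.pi, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_msd_invariant_under_rigid_motion(self, shift, angle, seed):
        coords = np.random.default_rng(seed).normal(size=(12, 2))
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        transformed = coords @ rot.T + np.asarray(shift)
        base = compute_msd(Trajectory(0, 0.1, coords), mode="ensemble")
        moved = compute_msd(Trajectory(0, 0.1, transformed), mode="ensemble")
        np.testing.assert_allclose(base.msd, moved.msd, rtol=1e-9, atol=1e-12)

    def test_ensemble_pools_pairs_across_trajectories(self):
        t1 = Trajectory(0, 1.0, np.array([[0.0, 0], [1, 0]]))  # MSD(1)=1, 1 pair
        t2 = Trajectory(1, 1.0, np.array([[0.0, 0], [3, 0], [6, 0]]))  # MSD(1)=9, 2 pairs
        profile = compute_msd([t1, t2], mode="ensemble")
        assert profile.msd_at(1.0) == pytest.approx((1 + 9 + 9) / 3)
        assert profile.msd_at(2.0) == pytest.approx(36.0)

    def test_mismatched_frame_intervals_rejected(self):
        t1 = Trajectory(0, 0.1, np.zeros((3, 2)))
        t2 = Trajectory(1, 0.2, np.zeros((3, 2)))
        with pytest.raises(ValueError, match="frame interval"):
            compute_msd([t1, t2])


class TestScaledMADFilter:
    def test_hand_worked_outlier(self):
        kept, flags = scaled_mad_filter([1.0, 2.0, 3.0, 4.0, 100.0])
        assert list(kept) == [1.0, 2.0, 3.0, 4.0]
        assert list(flags) == [False, False, False, False, True]

    def test_all_equal_values_kept(self):
        kept, flags = scaled_mad_filter([5.0] * 6)
        assert not flags.any() and len(kept) == 6

    def test_symmetric_tight_data_untouched(self):
        values = [-2.0, -1.0, 0.0, 1.0, 2.0]
        kept, flags = scaled_mad_filter(values)
        assert list(kept) == values

    def test_zero_mad_degenerate_rule(self):
        _, flags = scaled_mad_filter([1.0, 1.0, 1.0, 1.0, 2.0])
        assert list(flags) == [False] * 4 + [True]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            scaled_mad_filter([])


class TestTracking:
    def test_single_static_spot_tracked_full_length(self):
        detections = pd.DataFrame({"frame": range(15), "y": [10.0] * 15, "x": [12.0] * 15})
        trajectories = track_spots(detections, max_displacement=1.0, pixel_size=0.1)
        assert len(trajectories) == 1 and len(trajectories[0]) == 15
        assert np.allclose(trajectories[0].coords, [1.2, 1.0])  # µm, (x, y)

    def test_disappearing_spot_terminates_without_gap_closing(self):
        frames = list(range(5)) + list(range(8, 12))
        detections = pd.DataFrame({"frame": frames, "y": [10.0] * 9, "x": [10.0] * 9})
        trajectories = track_spots(detections, max_displacement=1.0, min_length=2, pixel_size=0.1)
        assert sorted(len(tr) for tr in trajectories) == [4, 5]

    def test_short_fragments_discarded(self):
        detections = pd.DataFrame({"frame": [0, 1, 2], "y": [1.0, 1.0, 1.0], "x": [1.0, 1.0, 1.0]})
        assert track_spots(detections, 1.0, min_length=5, pixel_size=0.1) == []

    def test_crossing_resolved_by_minimal_displacement(self):
        # two parallel spots; nearest-neighbour must not swap identities
        rows = []
        for t in range(10):
            rows.append({"frame": t, "y": 10.0, "x": 10.0 + t})
            rows.append({"frame": t, "y": 16.0, "x": 10.0 + t})
        trajectories = track_spots(pd.DataFrame(rows), max_displacement=5.0, pixel_size=1.0)
        assert len(trajectories) == 2
        ys = sorted(tr.coords[:, 1].mean() for tr in trajectories)
        assert np.allclose(ys, [10.0, 16.0])
        assert all(np.ptp(tr.coords[:, 1]) == 0 for tr in trajectories)


class TestMobilitySummaryAndFit:
    def _profiles(self, values, dt=0.1):
        profiles = []
        for i, v in enumerate(values):
            lags = dt * np.arange(1, 11)
            profiles.append(
                MSDProfile(trajectory_id=i, lags=lags, msd=np.full(10, v), n_pairs=np.full(10, 5))
            )
        return profiles

    def test_identical_trajectories_mean_is_common_score(self):
        summary = mobility_summary(self._profiles([0.3] * 6), lag_target=1.0)
        assert np.allclose(summary.scores["msd_at_lag"], 0.3)
        assert not summary.scores["outlier"].any()

    def test_short_trajectory_excluded_and_counted(self):
        short = MSDProfile(0, np.array([0.1, 0.2]), np.array([1.0, 1.0]), np.array([3, 2]))
        summary = mobility_summary([short], lag_target=1.0)
        assert summary.scores.empty and summary.n_excluded_short == 1

    def test_faster_condition_scores_higher(self):
        wins = 0
        for seed in range(10):
            means = {}
            for name, d in (("sparse", 0.02), ("dense", 0.01)):
                cfg = synthgen.MotionConfig(
                    seed=seed * 2 + (name == "dense"), n_trajectories=40,
                    n_frames=40, diffusion_coefficient=d,
                )
                trajectories, _ = synthgen.simulate_trajectories(cfg)
                profiles = compute_msd(trajectories, max_lag=1.0, mode="per_trajectory")
                summary = mobility_summary(profiles, lag_target=1.0)
                kept = summary.scores.loc[~summary.scores["outlier"], "msd_at_lag"]
                means[name] = kept.mean()
            wins += means["sparse"] > means["dense"]
        assert wins >= 9  # truth ordering recovered in >=95% of replicates

    def test_fit_on_exact_line(self):
        lags = 0.1 * np.arange(1, 11)
        profile = MSDProfile("e", lags, 4 * 0.01 * lags, np.full(10, 100))
        fit = fit_diffusion(profile)
        assert fit.diffusion_coefficient == pytest.approx(0.01)
        assert fit.offset == pytest.approx(0.0, abs=1e-12)

    def test_flat_profile_gives_zero_d(self):
        lags = 0.1 * np.arange(1, 11)
        fit = fit_diffusion(MSDProfile("e", lags, np.full(10, 0.4), np.full(10, 9)))
        assert fit.diffusion_coefficient == pytest.approx(0.0, abs=1e-12)
        assert fit.offset == pytest.approx(0.4)

    def test_parameter_recovery_with_localization_noise(self):
        d, sigma = 0.01, 0.02
        cfg = synthgen.MotionConfig(
            seed=77, n_trajectories=500, n_frames=100,
            diffusion_coefficient=d, localization_sd=sigma,
        )
        trajectories, _ = synthgen.simulate_trajectories(cfg)
        fit = fit_diffusion(compute_msd(trajectories, max_lag=1.0, mode="ensemble"))
        assert fit.diffusion_coefficient == pytest.approx(d, rel=0.10)
        assert fit.offset == pytest.approx(4 * sigma**2, rel=0.25)

    def test_moving_average_preserves_fitted_d_on_noiseless_tracks(self):
        # averaging positions reduces apparent short-lag MSD but the slope
        # at longer lags still reflects D; check the fit stays in tolerance
        d = 0.02
        cfg = synthgen.MotionConfig(seed=5, n_trajectories=400, n_frames=120,
                                    diffusion_coefficient=d, localization_sd=0.0)
        trajectories, _ = synthgen.simulate_trajectories(cfg)
        window = 5
        smoothed = []
        for tr in trajectories:
            kernel = np.ones(window) / window
            x = np.convolve(tr.coords[:, 0], kernel, mode="valid")
            y = np.convolve(tr.coords[:, 1], kernel, mode="valid")
            smoothed.append(Trajectory(tr.id, tr.frame_interval, np.column_stack([x, y])))
        raw_fit = fit_diffusion(compute_msd(trajectories, max_lag=3.0, mode="ensemble"))
        smooth_profile = compute_msd(smoothed, max_lag=3.0, mode="ensemble")
        keep = smooth_profile.lags >= window * 0.1  # beyond the averaging window
        smooth_fit = fit_diffusion(
            MSDProfile("e", smooth_profile.lags[keep], smooth_profile.msd[keep],
                       smooth_profile.n_pairs[keep])
        )
        assert smooth_fit.diffusion_coefficient == pytest.approx(
            raw_fit.diffusion_coefficient, rel=0.15
        )


class TestTrajectoryIO:
    def test_roundtrip_through_interchange_table(self):
        cfg = synthgen.MotionConfig(seed=3, n_trajectories=4, n_frames=10)
        trajectories, _ = synthgen.simulate_trajectories(cfg)
        table = motility.trajectories_to_frame(trajectories)
        rebuilt = motility.frame_to_trajectories(table)
        assert len(rebuilt) == 4
        for a, b in zip(trajectories, rebuilt):
            np.testing.assert_allclose(a.coords, b.coords)
            assert a.frame_interval == pytest.approx(b.frame_interval)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            motility.frame_to_trajectories(pd.DataFrame({"trajectory_id": [0]}))
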