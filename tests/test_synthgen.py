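"""Generator contracts: determinism, forward-model arithmetic, truth tables."""

import math

import numpy as np
import pandas as pd
import pytest

from repeatmeth import motility, synthgen
from repeatmeth.synthgen import (
    FlowSimConfig,
    MotionConfig,
    PlacementError,
    QPCRSimConfig,
    SceneConfig,
    simulate_flow_population,
    simulate_nuclei_stack,
    simulate_qpcr_plate,
    simulate_trajectories,
)


class TestSceneGeneration:
    def test_empty_scene_is_pure_background(self):
        cfg = SceneConfig(seed=0, n_nuclei=0, noise_sd=0.0)
        stack, truth = simulate_nuclei_stack(cfg)
        assert truth.nuclei.empty and truth.spots.empty
        assert np.allclose(stack.channel("reporter"), cfg.extranuclear_background)
        assert np.allclose(stack.channel("dna"), cfg.extranuclear_background)

    def test_noiseless_single_spot_peaks_at_amplitude_plus_background(self):
        cfg = SceneConfig(
            seed=3, n_nuclei=1, noise_sd=0.0,
            spots_per_nucleus_range=(1, 1), spot_amplitude=300.0,
        )
        stack, truth = simulate_nuclei_stack(cfg)
        reporter = stack.channel("reporter").max(axis=0)
        sy, sx = int(truth.spots.iloc[0]["y"]), int(truth.spots.iloc[0]["x"])
        expected = cfg.spot_amplitude + cfg.nuclear_background
        assert reporter[sy, sx] == pytest.approx(expected, rel=0.02)
        assert reporter.max() == pytest.approx(expected, rel=0.02)

    def test_spot_count_per_nucleus_matches_two_to_three(self):
        cfg = SceneConfig(seed=7, n_nuclei=50, image_width=640, image_height=640)
        _, truth = simulate_nuclei_stack(cfg)
        per_nucleus = truth.spots.groupby("nucleus_id").size()
        assert len(per_nucleus) == 50
        assert 2.0 <= per_nucleus.mean() <= 3.0
        assert set(per_nucleus.unique()) <= {2, 3}

    def test_spots_lie_inside_their_nucleus(self, small_scene):
        _, _, truth = small_scene
        merged = truth.spots.merge(truth.nuclei, on="nucleus_id", suffixes=("_s", "_n"))
        dist = np.hypot(merged["y_s"] - merged["y_n"], merged["x_s"] - merged["x_n"])
        assert (dist <= merged["radius"]).all()

    def test_seed_determinism_is_byte_identical(self):
        cfg = SceneConfig(seed=5, n_nuclei=4)
        s1, t1 = simulate_nuclei_stack(cfg, "dense")
        s2, t2 = simulate_nuclei_stack(cfg, "dense")
        assert np.array_equal(s1.pixels, s2.pixels)
        pd.testing.assert_frame_equal(t1.spots, t2.spots)

    def test_truth_identifiers_are_unique(self, small_scene):
        _, _, truth = small_scene
        assert truth.nuclei["nucleus_id"].is_unique
        assert truth.spots["spot_id"].is_unique

    def test_overcrowded_scene_raises_naming_the_limit(self):
        cfg = SceneConfig(seed=0, n_nuclei=60, image_width=128, image_height=128)
        with pytest.raises(PlacementError, match="n_nuclei"):
            simulate_nuclei_stack(cfg)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="preset"):
            simulate_nuclei_stack(SceneConfig(n_nuclei=1), "no_such_condition")


class TestTrajectories:
    def test_frozen_motion_is_constant(self):
        cfg = MotionConfig(seed=0, diffusion_coefficient=0.0, localization_sd=0.0,
                           n_trajectories=5, n_frames=20)
        trajectories, _ = simulate_trajectories(cfg)
        for tr in trajectories:
            assert np.allclose(tr.coords, tr.coords[0])

    def test_brownian_ensemble_msd_matches_4dt(self):
        d = 0.01
        cfg = MotionConfig(seed=11, n_trajectories=500, n_frames=100,
                           diffusion_coefficient=d, localization_sd=0.0)
        trajectories, _ = simulate_trajectories(cfg)
        profile = motility.compute_msd(trajectories, max_lag=1.0, mode="ensemble")
        assert np.allclose(profile.msd, 4 * d * profile.lags, rtol=0.10)

    def test_pure_localization_noise_gives_flat_4sigma2(self):
        sigma = 0.03
        cfg = MotionConfig(seed=13, n_trajectories=400, n_frames=60,
                           diffusion_coefficient=0.0, localization_sd=sigma)
        trajectories, _ = simulate_trajectories(cfg)
        profile = motility.compute_msd(trajectories, max_lag=1.0, mode="ensemble")
        assert np.allclose(profile.msd, 4 * sigma**2, rtol=0.10)

    def test_confined_msd_plateau_bounded(self):
        radius, sigma = 0.15, 0.01
        cfg = MotionConfig(seed=17, n_trajectories=300, n_frames=200,
                           diffusion_coefficient=0.05, localization_sd=sigma,
                           motion_model="confined", confinement_radius=radius)
        trajectories, _ = simulate_trajectories(cfg)
        profile = motility.compute_msd(trajectories, max_lag=10.0, mode="ensemble")
        bound = 2 * radius**2 + 4 * sigma**2
        assert profile.msd[-10:].max() <= bound * 1.05

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            simulate_trajectories(MotionConfig(n_frames=1))

    def test_confined_requires_radius(self):
        with pytest.raises(ValueError, match="confinement_radius"):
            MotionConfig(motion_model="confined").validate()


class TestMovieRendering:
    def test_static_noiseless_spot_gives_identical_frames(self):
        traj = motility.Trajectory(id=0, frame_interval=0.1,
                                   coords=np.tile([5.0, 5.0], (10, 1)))
        cfg = SceneConfig(seed=0, noise_sd=0.0)
        movie = synthgen.render_movie([traj], cfg)
        frames = movie.channel("reporter")
        assert all(np.array_equal(frames[0], frames[t]) for t in range(1, 10))
        assert movie.frame_interval == 0.1

    def test_empty_trajectory_list_is_pure_background(self):
        cfg = SceneConfig(seed=0, noise_sd=0.0)
        movie = synthgen.render_movie([], cfg)
        assert np.allclose(movie.pixels, cfg.extranuclear_background)

    def test_out_of_field_coordinate_names_trajectory_and_frame(self):
        coords = np.tile([5.0, 5.0], (5, 1))
        coords[3] = [999.0, 5.0]
        traj = motility.Trajectory(id=7, frame_interval=0.1, coords=coords)
        with pytest.raises(ValueError, match=r"trajectory 7 .* frame 3"):
            synthgen.render_movie([traj], SceneConfig())

    def test_tracker_recovers_two_separated_drifting_spots(self):
        dt, n = 0.1, 30
        t = np.arange(n)
        a = np.column_stack([2.0 + 0.01 * t, 2.0 + 0.01 * t])
        b = np.column_stack([20.0 - 0.01 * t, 20.0 + 0.01 * t])
        trajs = [motility.Trajectory(id=i, frame_interval=dt, coords=c)
                 for i, c in enumerate((a, b))]
        cfg = SceneConfig(seed=0, noise_sd=0.0)
        movie = synthgen.render_movie(trajs, cfg)
        detections = motility.detect_spots(movie)
        recovered = motility.track_spots(
            detections, max_displacement=0.5, min_length=n,
            pixel_size=cfg.pixel_size, frame_interval=dt,
        )
        assert len(recovered) == 2
        assert all(len(tr) == n for tr in recovered)


class TestQPCRPlate:
    def _clean(self, fraction, efficiency=2.0):
        cfg = QPCRSimConfig(
            conditions=(("only", fraction, 1.0),), technical_sd=0.0, biological_sd=0.0,
            efficiency=efficiency, n_biological=1, include_expression=False,
        )
        plate = simulate_qpcr_plate(cfg)
        by_role = plate.groupby("primer_role")["ct"].mean()
        return by_role["msre_target"] - by_role["msre_control"]

    def test_fully_protected_template_has_equal_cts(self):
        assert self._clean(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_protected_template_delays_one_cycle(self):
        assert self._clean(0.5) == pytest.approx(1.0, abs=1e-12)

    def test_ten_percent_protection_delay_is_log2_ten(self):
        assert self._clean(0.1) == pytest.approx(math.log2(10), abs=1e-9)

    def test_zero_fraction_gives_undetermined_sentinel(self):
        cfg = QPCRSimConfig(conditions=(("gone", 0.0, 1.0),), n_biological=1,
                            include_expression=False)
        plate = simulate_qpcr_plate(cfg)
        assert plate.loc[plate["primer_role"] == "msre_target", "ct"].isna().all()
        assert plate.loc[plate["primer_role"] == "msre_control", "ct"].notna().all()

    def test_per_site_model_compounds_protection(self):
        cfg = QPCRSimConfig(
            conditions=(("s", 0.9, 1.0),), technical_sd=0.0, biological_sd=0.0,
            n_biological=1, include_expression=False, per_site_count=6,
        )
        plate = simulate_qpcr_plate(cfg)
        by_role = plate.groupby("primer_role")["ct"].mean()
        assert by_role["msre_target"] - by_role["msre_control"] == pytest.approx(
            -6 * math.log2(0.9), abs=1e-9
        )

    def test_seed_determinism(self):
        cfg = synthgen.qpcr_preset("mcf10a_aza", seed=9)
        pd.testing.assert_frame_equal(simulate_qpcr_plate(cfg), simulate_qpcr_plate(cfg))

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError, match="efficiency"):
            QPCRSimConfig(efficiency=2.5).validate()


class TestFlowPopulation:
    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            FlowSimConfig(n_events=0).validate()

    def test_negative_fraction_bounds(self):
        with pytest.raises(ValueError, match="negative_fraction"):
            FlowSimConfig(negative_fraction=1.5).validate()

    def test_shift_factor_scales_positive_median(self):
        cfg = FlowSimConfig(seed=21, negative_fraction=0.0)
        base = simulate_flow_population(cfg, shift_factor=1.0)
        half = simulate_flow_population(cfg, shift_factor=0.5)
        m_base = base.loc[base["sample_id"] == "sample", "intensity"].median()
        m_half = half.loc[half["sample_id"] == "sample", "intensity"].median()
        assert m_half / m_base == pytest.approx(0.5, rel=1e-9)  # same seed: exact scaling

    def test_control_contains_only_negative_component(self):
        cfg = FlowSimConfig(seed=22)
        events = simulate_flow_population(cfg, shift_factor=1.0)
        control = events.loc[events["sample_id"] == "parental_control", "intensity"]
        sample = events.loc[events["sample_id"] == "sample", "intensity"]
        assert control.median() < sample.median() / 5
        assert len(control) == cfg.n_events
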