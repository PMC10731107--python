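import numpy as np
import pytest

from spineqct.errors import ValidationError
from spineqct.synthetic import (DEFAULT_MISSION_POOL, CohortConfig, GridSpec,
                                LinearHUMap, MuscleSpec, PhantomSpec,
                                VertebraSpec, default_muscles, generate_cohort,
                                render_session, sample_trajectories)


class TestSpecValidation:
    def test_negative_density_names_field(self):
        spec = VertebraSpec(regional_trabecular_density={
            "superior": -1.0, "transverse": 170.0, "inferior": 180.0})
        with pytest.raises(ValidationError, match="regional_trabecular_density"):
            spec.validate()

    def test_shell_thicker_than_half_height_rejected(self):
        with pytest.raises(ValidationError, match="body_height"):
            VertebraSpec(body_height=8.0).validate()

    def test_muscle_window_invariant(self):
        with pytest.raises(ValidationError, match="lean_hu"):
            MuscleSpec("psoas_major", "left", (0, 0), 100.0, fat_hu=-20.0).validate()

    def test_phantom_needs_two_distinct_rods(self):
        with pytest.raises(ValidationError, match="distinct"):
            PhantomSpec(rod_nominal_densities=(100.0, 100.0),
                        rod_positions=((0, -40), (20, -40))).validate()

    def test_overlapping_rods_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PhantomSpec(rod_nominal_densities=(0.0, 100.0),
                        rod_positions=((0, -40), (4, -40))).validate()


class TestRenderSession:
    def test_regional_mean_hu_matches_injected_density(self, noiseless_scene, grid):
        # identity calibration, no noise: superior-region voxels sit at
        # exactly the injected 178.9 HU
        vol, labels, _ = noiseless_scene
        z = grid.slice_centers_z()
        sup_slices = np.flatnonzero((z > 3.0) & (np.abs(z) <= 12.0))
        sup = np.zeros(vol.shape, bool)
        sup[:, :, sup_slices] = labels.data[:, :, sup_slices] == 1
        assert vol.data[sup].mean() == pytest.approx(178.9, abs=1e-9)

    def test_uniform_densities_give_constant_trabecular_field(self, grid):
        vert = VertebraSpec(regional_trabecular_density={
            "superior": 170.0, "transverse": 170.0, "inferior": 170.0})
        vol, labels, _ = render_session(
            vert, default_muscles(), PhantomSpec(), LinearHUMap(1.0, 0.0),
            0.0, np.random.default_rng(0), grid)
        assert np.ptp(vol.data[labels.data == 1]) == 0.0

    def test_masks_consistent_with_volume(self, noiseless_scene):
        # every rod voxel carries that rod's nominal HU (identity calibration)
        vol, labels, legend = noiseless_scene
        for lab, rho in legend["rods"].items():
            assert np.allclose(vol.data[labels.data == int(lab)], rho)

    def test_invalid_spec_raises_named_error(self, grid):
        bad = VertebraSpec(cortical_thickness=-1.0)
        with pytest.raises(ValidationError, match="cortical_thickness"):
            render_session(bad, [], PhantomSpec(), LinearHUMap(1.0, 0.0),
                           0.0, np.random.default_rng(0), grid)


class TestCohortDesign:
    def test_mission_multiset_mean(self):
        # {4x2, 5x3, 6x7, 7x5} averages to 5.88 months (prints as 5.9)
        assert np.mean(DEFAULT_MISSION_POOL) == pytest.approx(100 / 17)
        assert round(float(np.mean(DEFAULT_MISSION_POOL)), 2) == 5.88

    def test_followup_omitted_for_last_subjects(self):
        cfg = CohortConfig(n_subjects=4, n_followup=2, seed=3)
        trajs = sample_trajectories(cfg, np.random.default_rng(3))
        assert [t.has_followup for t in trajs] == [True, True, False, False]

    def test_standardized_draws_hit_target_moments(self):
        cfg = CohortConfig(seed=5, standardize_draws=True)
        trajs = sample_trajectories(cfg, np.random.default_rng(5))
        sup = np.array([t.flight_rate_per_region["superior"] for t in trajs])
        assert sup.mean() == pytest.approx(-1.08, abs=1e-9)
        assert sup.std(ddof=1) == pytest.approx(1.13, abs=1e-9)

    def test_preflight_offset_is_identity(self):
        cfg = CohortConfig(n_subjects=2, n_followup=1, seed=1)
        for t in sample_trajectories(cfg, np.random.default_rng(1)):
            ang, tr = t.session_offsets["preflight"]
            assert ang == (0.0, 0.0, 0.0) and tr == (0.0, 0.0, 0.0)

    def test_invalid_config_names_field(self):
        with pytest.raises(ValidationError, match="n_followup"):
            CohortConfig(n_subjects=3, n_followup=5).validate()


class TestGenerateCohort:
    def test_seed_determinism_bit_identical(self):
        cfg = CohortConfig(n_subjects=1, n_followup=1, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.truth.equals(b.truth)
        for sa, sb in zip(a.subjects, b.subjects):
            for sess in sa.sessions:
                assert np.array_equal(sa.sessions[sess].volume.data,
                                      sb.sessions[sess].volume.data)
                assert np.array_equal(sa.sessions[sess].labels.data,
                                      sb.sessions[sess].labels.data)

    def test_truth_percent_change_is_exact(self):
        cfg = CohortConfig(n_subjects=2, n_followup=1, seed=9)
        truth = generate_cohort(cfg).truth
        post = truth[truth.session == "postflight"]
        for r in ("superior", "transverse", "inferior"):
            expected = post[f"flight_rate_{r}"] * post["mission_months"]
            assert np.allclose(post[f"true_percent_{r}"], expected, atol=1e-9)

    def test_zero_rates_freeze_anatomy(self):
        zero = (0.0, 0.0)
        cfg = CohortConfig(
            n_subjects=1, n_followup=1, seed=4, noise_sd=0.0,
            flight_rate={r: zero for r in ("superior", "transverse", "inferior")},
            readapt_rate={r: zero for r in ("superior", "transverse", "inferior")},
            muscle_csa_flight=zero, muscle_density_flight=zero,
            muscle_csa_readapt=zero, muscle_density_readapt=zero,
            max_translation_mm=0.0, max_rotation_deg=0.0,
        )
        cohort = generate_cohort(cfg)
        subj = cohort.subjects[0]
        pre = subj.sessions["preflight"].volume.data
        for sess in ("postflight", "followup"):
            # identical up to the (absent) offset and (absent) noise, except
            # for the per-session Bernoulli fat pattern inside muscle labels
            same = subj.sessions[sess].volume.data
            nonmuscle = subj.sessions[sess].labels.data < 20
            assert np.array_equal(pre[nonmuscle], same[nonmuscle])

    def test_written_cohort_round_trips(self, tmp_path):
        from spineqct.pipeline import load_cohort_from_disk

        cfg = CohortConfig(n_subjects=1, n_followup=0, seed=2)
        cohort = generate_cohort(cfg, out_dir=tmp_path)
        assert (tmp_path / "ground_truth.csv").exists()
        loaded = load_cohort_from_disk(tmp_path, cfg)
        orig = cohort.subjects[0].sessions["preflight"].volume.data
        back = loaded.subjects[0].sessions["preflight"].volume.data
        assert np.allclose(orig, back, atol=1e-5)
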