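import numpy as np
import pytest

from lfoamp import (
    Band,
    NoiseModel,
    PlantedEffect,
    ScoreModel,
    SyntheticSpec,
    VolumeGrid,
    amplitude_spectrum,
    compute_alff,
    generate_cohort,
    make_brain_mask,
    simulate_bold,
    simulate_gm_map,
    simulate_records,
    two_sample_t_map,
)

QUIET = NoiseModel(white_sd=0.0, physio_components=(), drift_slope_per_vol=0.0)


def quiet_spec(grid, components=((0.05, 2.0),), effects=(), **kw):
    """Noise-free spec: deterministic sinusoids only."""
    return SyntheticSpec(
        n_per_group=2,
        grid=grid,
        n_volumes_acquired=50,
        base_band_components=components,
        effects=effects,
        noise=QUIET,
        subject_amp_cv=0.0,
        voxel_amp_cv=0.0,
        seed=5,
        **kw,
    )


class TestBrainMask:
    def test_ellipsoid_count_matches_brute_force(self):
        grid = VolumeGrid.default((64, 64, 30))
        semi = (24.0, 30.0, 21.0)
        mask = make_brain_mask(grid, semi)
        # independent brute-force voxel-center count
        count = 0
        for i in range(64):
            for j in range(64):
                for k in range(30):
                    x, y, z = grid.voxel_to_mm(np.array([i, j, k]))
                    if (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1:
                        count += 1
        assert mask.n_voxels == count
        assert 2000 <= mask.n_voxels <= 4000

    def test_degenerate_axes_rejected(self, small_grid):
        with pytest.raises(ValueError):
            make_brain_mask(small_grid, (0.0, 0.0, 0.0))

    def test_centered_mask_symmetric_under_x_reflection(self, small_grid):
        mask = make_brain_mask(small_grid, (12.0, 14.0, 10.0))
        assert np.array_equal(mask.include, mask.include[::-1])


class TestSimulateBold:
    def test_zero_noise_single_component_is_exact_sinusoid(self, small_grid):
        spec = quiet_spec(small_grid)
        rec = simulate_records(spec)[0]
        run = simulate_bold(spec, rec)
        brain = spec.brain_mask().include
        series = run.data[brain][0] - spec.baseline
        _, amps = amplitude_spectrum(series, spec.tr_s)
        k = int(round(0.05 * run.n_volumes * spec.tr_s))
        assert amps[k] == pytest.approx(2.0, abs=1e-9)
        assert np.max(np.abs(np.delete(amps, k))) < 1e-9

    def test_patient_in_sphere_scaled_by_amplitude_ratio(self, small_grid):
        eff = PlantedEffect(center_mm=(0, 0, 0), radius_mm=6.0, amplitude_ratio=1.5)
        spec = quiet_spec(small_grid, effects=(eff,))
        records = simulate_records(spec)
        patient = next(r for r in records if r.group == "patient")
        control = next(r for r in records if r.group == "control")
        sphere = eff.member_mask(small_grid)
        brain = spec.brain_mask().include
        p_run = simulate_bold(spec, patient)
        c_run = simulate_bold(spec, control)
        k = int(round(0.05 * p_run.n_volumes * spec.tr_s))
        p_amp = amplitude_spectrum(p_run.data[sphere & brain][0], spec.tr_s)[1][k]
        c_amp = amplitude_spectrum(c_run.data[sphere & brain][0], spec.tr_s)[1][k]
        assert p_amp / c_amp == pytest.approx(1.5, abs=1e-6)

    def test_deterministic_in_seed_and_subject(self, small_grid):
        spec = SyntheticSpec(n_per_group=1, grid=small_grid, n_volumes_acquired=30, seed=9)
        rec = simulate_records(spec)[0]
        a = simulate_bold(spec, rec)
        b = simulate_bold(spec, rec)
        assert np.array_equal(a.data, b.data)
        other = simulate_bold(spec, rec, seed=10)
        assert not np.array_equal(a.data, other.data)

    def test_alff_ratio_two_recovered_downstream(self, small_grid):
        """With a ratio-2 sphere and zero noise, patient ALFF inside vs
        outside the sphere differs by exactly the planted factor."""
        eff = PlantedEffect(center_mm=(0, 0, 0), radius_mm=6.0, amplitude_ratio=2.0)
        spec = quiet_spec(small_grid, effects=(eff,))
        patient = next(r for r in simulate_records(spec) if r.group == "patient")
        amap = compute_alff(simulate_bold(spec, patient), Band(0.01, 0.08))
        brain = spec.brain_mask().include
        sphere = eff.member_mask(small_grid)
        inside = amap.values[sphere & brain].mean()
        outside = amap.values[brain & ~sphere].mean()
        assert inside / outside == pytest.approx(2.0, abs=1e-6)

    def test_component_above_nyquist_rejected(self, small_grid):
        spec = quiet_spec(small_grid, components=((0.3, 1.0),))
        rec = simulate_records(spec)[0]
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_bold(spec, rec)

    def test_spectral_ground_truth_matches_component_set(self, small_grid):
        """Noise disabled: the DFT amplitude spectrum is exactly the
        constructed component set at every in-mask voxel."""
        comps = ((0.02, 1.2), (0.06, 0.5))
        spec = quiet_spec(small_grid, components=comps)
        rec = simulate_records(spec)[0]
        run = simulate_bold(spec, rec)
        brain = spec.brain_mask().include
        series = run.data[brain][-1] - spec.baseline
        freqs, amps = amplitude_spectrum(series, spec.tr_s)
        for f, a in comps:
            k = int(round(f * run.n_volumes * spec.tr_s))
            assert amps[k] == pytest.approx(a, abs=1e-9)
            amps[k] = 0.0
        assert np.max(np.abs(amps)) < 1e-9


class TestSimulateGmMap:
    def test_no_noise_gives_constant_mean_level(self, small_grid):
        from dataclasses import replace

        spec = replace(quiet_spec(small_grid), gm_noise_sd=0.0, gm_smoothness_mm=0.0)
        rec = simulate_records(spec)[0]
        gm = simulate_gm_map(spec, rec)
        brain = spec.brain_mask().include
        assert np.allclose(gm[brain], spec.gm_mean_level)
        assert np.allclose(gm[~brain], 0.0)

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_values_always_within_unit_interval(self, small_grid, seed):
        spec = SyntheticSpec(
            n_per_group=1, grid=small_grid, n_volumes_acquired=20,
            gm_noise_sd=0.5, seed=seed,
        )
        rec = simulate_records(spec)[0]
        gm = simulate_gm_map(spec, rec)
        assert gm.min() >= 0.0
        assert gm.max() <= 1.0

    def test_planted_gm_reduction_monte_carlo_mean(self, small_grid):
        """Ratio-0.8 GM sphere: patient-minus-control mean inside the sphere
        approaches -0.2 * mean_level over many subjects."""
        eff = PlantedEffect(
            center_mm=(0, 0, 0), radius_mm=7.0, amplitude_ratio=0.8,
            applies_to="gm_volume",
        )
        spec = SyntheticSpec(
            n_per_group=100, grid=small_grid, n_volumes_acquired=20,
            effects=(eff,), seed=21,
        )
        records = simulate_records(spec)
        sphere = eff.member_mask(small_grid) & spec.brain_mask().include
        means = {"patient": [], "control": []}
        for rec in records:
            means[rec.group].append(simulate_gm_map(spec, rec)[sphere].mean())
        diff = np.mean(means["patient"]) - np.mean(means["control"])
        expected = -0.2 * spec.gm_mean_level
        se = np.sqrt(
            np.var(means["patient"], ddof=1) / 100 + np.var(means["control"], ddof=1) / 100
        )
        assert diff == pytest.approx(expected, abs=max(3 * se, 0.01))

    def test_invalid_mean_level_rejected(self, small_grid):
        with pytest.raises(ValueError, match="gm_mean_level"):
            SyntheticSpec(grid=small_grid, gm_mean_level=1.5)


class TestCohortGeneration:
    def test_file_layout_and_counts(self, tiny_cohort):
        spec, manifest, out = tiny_cohort
        assert manifest.group_counts() == {"patient": 3, "control": 3}
        assert len(list(out.glob("*_bold.nii.gz"))) == 6
        assert len(list(out.glob("*_gm.nii.gz"))) == 6
        assert (out / "manifest.tsv").exists()

    def test_single_subject_groups_refuse_downstream_t_test(self, small_grid):
        spec = SyntheticSpec(
            n_per_group=1, grid=small_grid, n_volumes_acquired=20, seed=2
        )
        records = simulate_records(spec)
        assert len(records) == 2
        mask = spec.brain_mask()
        one_map = [np.ones(small_grid.dims)]
        with pytest.raises(ValueError, match=">= 2 subjects"):
            two_sample_t_map(one_map, one_map, mask)

    def test_zero_subjects_rejected(self, small_grid):
        with pytest.raises(ValueError, match="n_per_group"):
            simulate_records(SyntheticSpec(n_per_group=0, grid=small_grid))

    def test_patient_hrsd_sampling_mean(self, small_grid):
        """Patient HRSD draws average ~25 (500 patients, sampling check)."""
        spec = SyntheticSpec(n_per_group=500, grid=small_grid, seed=31)
        records = simulate_records(spec)
        hrsd = [r.hrsd_total for r in records if r.group == "patient"]
        assert np.mean(hrsd) == pytest.approx(25.0, abs=0.5)
        # controls are screened at HRSD < 7, so their draws follow a normal
        # truncated to [0, 6]; compare against the closed-form truncated mean
        from scipy.stats import truncnorm

        controls = [r.hrsd_total for r in records if r.group == "control"]
        expected = truncnorm.mean((0 - 4) / 3, (6 - 4) / 3, loc=4, scale=3)
        assert np.mean(controls) == pytest.approx(expected, abs=0.5)
        assert max(controls) <= 6
        assert min(hrsd) >= 0

    def test_hrsd_floor_option(self, small_grid):
        spec = SyntheticSpec(
            n_per_group=50, grid=small_grid, seed=31,
            score_model=ScoreModel(floor_patient_hrsd_at_24=True),
        )
        hrsd = [r.hrsd_total for r in simulate_records(spec) if r.group == "patient"]
        assert min(hrsd) >= 24

    def test_motion_below_screening_thresholds(self, small_grid):
        records = simulate_records(SyntheticSpec(n_per_group=18, grid=small_grid))
        for r in records:
            assert max(r.motion.max_translation_mm) < 1.0
            assert max(r.motion.max_rotation_deg) < 1.0

    def test_spec_json_roundtrip(self, small_grid, tmp_path):
        eff = PlantedEffect(center_mm=(3, 0, 0), radius_mm=6.0, amplitude_ratio=1.5)
        spec = SyntheticSpec(
            n_per_group=4, grid=small_grid, n_volumes_acquired=30,
            effects=(eff,), seed=11,
        )
        back = SyntheticSpec.from_json(spec.to_json(tmp_path / "spec.json"))
        assert back == spec
        # lossless: the round-tripped spec generates identical data
        rec = simulate_records(spec)[0]
        assert np.array_equal(
            simulate_bold(spec, rec).data, simulate_bold(back, rec).data
        )

    def test_regeneration_is_byte_identical(self, small_grid, tmp_path):
        spec = SyntheticSpec(n_per_group=1, grid=small_grid, n_volumes_acquired=16, seed=77)
        generate_cohort(spec, tmp_path / "a")
        generate_cohort(spec, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
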