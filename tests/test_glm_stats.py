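import numpy as np
import pytest
from scipy import stats

from lfoamp import (
    BrainMask,
    DesignInfo,
    PlantedEffect,
    SyntheticSpec,
    correlation_map,
    glm_t_map,
    gm_group_difference,
    simulate_gm_map,
    simulate_records,
    two_sample_t_map,
)
from lfoamp.glm_stats import r_to_t


@pytest.fixture
def full_mask(small_grid):
    return BrainMask(small_grid, np.ones(small_grid.dims, dtype=bool))


def random_maps(rng, grid, n, loc=1.0):
    return [loc + 0.1 * rng.normal(size=grid.dims) for _ in range(n)]


class TestTwoSampleT:
    def test_identical_groups_give_zero(self, small_grid, full_mask, rng):
        maps = random_maps(rng, small_grid, 4)
        smap = two_sample_t_map(maps, [m.copy() for m in maps], full_mask)
        assert np.allclose(smap.statistic, 0.0)
        assert smap.df == 6

    def test_swapping_groups_flips_sign(self, small_grid, full_mask, rng):
        a = random_maps(rng, small_grid, 5)
        b = random_maps(rng, small_grid, 4)
        ab = two_sample_t_map(a, b, full_mask).statistic
        ba = two_sample_t_map(b, a, full_mask).statistic
        assert np.allclose(ab, -ba, atol=1e-12)

    def test_matches_scipy_pooled_t(self, small_grid, full_mask, rng):
        """4+4 subjects against the scipy.stats.ttest_ind oracle, voxelwise."""
        a = random_maps(rng, small_grid, 4)
        b = random_maps(rng, small_grid, 4)
        smap = two_sample_t_map(a, b, full_mask)
        oracle = stats.ttest_ind(np.stack(a), np.stack(b), axis=0, equal_var=True)
        assert np.max(np.abs(smap.statistic - oracle.statistic)) < 1e-10

    def test_small_group_rejected(self, small_grid, full_mask, rng):
        a = random_maps(rng, small_grid, 1)
        b = random_maps(rng, small_grid, 4)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            two_sample_t_map(a, b, full_mask)

    def test_zero_variance_voxels_counted_and_zeroed(self, small_grid, full_mask):
        a = [np.ones(small_grid.dims) for _ in range(3)]
        b = [np.ones(small_grid.dims) for _ in range(3)]
        smap = two_sample_t_map(a, b, full_mask)
        assert np.allclose(smap.statistic, 0.0)
        assert smap.n_degenerate == small_grid.n_voxels


class TestGlmTMap:
    def _design(self, n_a, n_b, **kw):
        return DesignInfo(
            contrast_name="group",
            group_labels=["patient"] * n_a + ["control"] * n_b,
            **kw,
        )

    def test_no_covariates_equals_two_sample_t(self, small_grid, full_mask, rng):
        a = random_maps(rng, small_grid, 6)
        b = random_maps(rng, small_grid, 5)
        pooled = two_sample_t_map(a, b, full_mask).statistic
        glm = glm_t_map(a + b, self._design(6, 5), full_mask).statistic
        assert np.max(np.abs(pooled - glm)) < 1e-10

    def test_orthogonal_covariate_leaves_group_t_unchanged(self, small_grid, full_mask, rng):
        """A regressor orthogonal to both the group indicator and the data
        changes neither the group estimate nor (at matched df accounting)
        its t beyond 1e-8."""
        n = 8
        y_vec = rng.normal(size=n)
        maps = [np.full(small_grid.dims, v) for v in y_vec]
        g = np.array([1.0] * 4 + [0.0] * 4)
        basis = np.column_stack([np.ones(n), g, y_vec])
        q, _ = np.linalg.qr(basis)
        c = rng.normal(size=n)
        c -= q @ (q.T @ c)  # orthogonal to 1, group and amplitude
        base = glm_t_map(maps, self._design(4, 4), full_mask)
        with_c = glm_t_map(
            maps, self._design(4, 4, scalar_covariates={"c": c}), full_mask
        )
        # same group coefficient => t ratio is only the df/sigma scaling
        t0 = base.statistic[0, 0, 0]
        t1 = with_c.statistic[0, 0, 0]
        scale = np.sqrt((n - 2) / (n - 3))  # rss unchanged, df differs
        assert t1 == pytest.approx(t0 / scale, abs=1e-8)

    def test_collinear_voxelwise_covariate_excluded(self, small_grid, full_mask, rng):
        n = 6
        maps = random_maps(rng, small_grid, n)
        g = np.array([1.0] * 3 + [0.0] * 3)
        collinear = np.stack(
            [np.full(small_grid.dims, v) for v in g]
        )  # identical to the group column at every voxel
        design = self._design(3, 3, voxelwise_covariates={"gm": collinear})
        smap = glm_t_map(maps, design, full_mask)
        assert smap.mask.n_voxels == 0
        assert smap.n_degenerate == small_grid.n_voxels

    def test_matches_statsmodels_at_sampled_voxels(self, small_grid, full_mask, rng):
        """Independent per-voxel OLS oracle (statsmodels) for the full design
        with age and a voxelwise covariate."""
        import statsmodels.api as sm

        n = 12
        maps = random_maps(rng, small_grid, n)
        ages = rng.uniform(20, 60, size=n)
        gm = rng.normal(size=(n, *small_grid.dims))
        design = self._design(
            6, 6, scalar_covariates={"age": ages}, voxelwise_covariates={"gm": gm}
        )
        smap = glm_t_map(maps, design, full_mask)
        g = design.group_indicator()
        y_all = np.stack([m for m in maps])
        flat_idx = rng.choice(small_grid.n_voxels, size=20, replace=False)
        for fi in flat_idx:
            ijk = np.unravel_index(fi, small_grid.dims)
            y = y_all[(slice(None), *ijk)]
            gm_v = gm[(slice(None), *ijk)]
            x = np.column_stack(
                [np.ones(n), g, ages - ages.mean(), gm_v - gm_v.mean()]
            )
            fit = sm.OLS(y, x).fit()
            assert smap.statistic[ijk] == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert smap.df == n - 4


class TestCorrelationMap:
    def test_perfect_correlation(self, small_grid, full_mask):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        maps = [np.full(small_grid.dims, s) for s in scores]
        smap = correlation_map(maps, scores, full_mask)
        assert np.allclose(smap.statistic, 1.0)
        assert smap.kind == "r"
        assert smap.df == 3

    def test_constant_scores_rejected(self, small_grid, full_mask, rng):
        maps = random_maps(rng, small_grid, 5)
        with pytest.raises(ValueError, match="constant"):
            correlation_map(maps, np.full(5, 3.0), full_mask)

    def test_too_few_subjects_rejected(self, small_grid, full_mask, rng):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_map(random_maps(rng, small_grid, 2), np.array([1.0, 2.0]), full_mask)

    def test_matches_covariance_formula(self, small_grid, full_mask, rng):
        """18 random pairs against the direct covariance-formula oracle."""
        n = 18
        maps = random_maps(rng, small_grid, n)
        scores = rng.normal(size=n)
        smap = correlation_map(maps, scores, full_mask)
        y = np.stack(maps)
        for ijk in [(0, 0, 0), (5, 7, 3), (11, 11, 9)]:
            v = y[(slice(None), *ijk)]
            num = np.sum((v - v.mean()) * (scores - scores.mean()))
            den = np.sqrt(np.sum((v - v.mean()) ** 2) * np.sum((scores - scores.mean()) ** 2))
            assert smap.statistic[ijk] == pytest.approx(num / den, abs=1e-12)

    def test_r_to_t_matches_regression_t(self, small_grid, full_mask, rng):
        """r converted through t = r sqrt(df/(1-r^2)) equals the OLS slope t
        of amplitude on score (statsmodels oracle)."""
        import statsmodels.api as sm

        n = 15
        maps = random_maps(rng, small_grid, n)
        scores = rng.normal(size=n)
        smap = correlation_map(maps, scores, full_mask)
        y = np.stack(maps)
        for ijk in [(1, 2, 3), (8, 4, 6)]:
            fit = sm.OLS(
                y[(slice(None), *ijk)], np.column_stack([np.ones(n), scores])
            ).fit()
            t_from_r = r_to_t(smap.statistic[ijk], smap.df)
            assert t_from_r == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_partial_r_matches_pingouin(self, small_grid, full_mask, rng):
        """Scalar-covariate partial correlation against the pingouin oracle."""
        import pandas as pd
        import pingouin as pg

        n = 20
        maps = random_maps(rng, small_grid, n)
        scores = rng.normal(size=n)
        age = rng.uniform(20, 60, size=n)
        smap = correlation_map(
            maps, scores, full_mask, partial_covariates={"age": age}
        )
        assert smap.df == n - 3
        y = np.stack(maps)
        for ijk in [(2, 2, 2), (9, 10, 4)]:
            df = pd.DataFrame(
                {"y": y[(slice(None), *ijk)], "s": scores, "age": age}
            )
            oracle = pg.partial_corr(df, x="s", y="y", covar="age")["r"].iloc[0]
            assert smap.statistic[ijk] == pytest.approx(oracle, abs=1e-8)


class TestGmGroupDifference:
    def test_identical_groups_zero(self, small_grid, full_mask, rng):
        maps = random_maps(rng, small_grid, 4, loc=0.5)
        smap = gm_group_difference(maps, [m.copy() for m in maps], full_mask)
        assert np.allclose(smap.statistic, 0.0)

    def test_matches_pooled_t_when_presmoothed(self, small_grid, full_mask, rng):
        a = random_maps(rng, small_grid, 4, loc=0.5)
        b = random_maps(rng, small_grid, 4, loc=0.5)
        smap = gm_group_difference(a, b, full_mask, presmoothed=True)
        oracle = stats.ttest_ind(np.stack(a), np.stack(b), axis=0, equal_var=True)
        assert np.max(np.abs(smap.statistic - oracle.statistic)) < 1e-10

    def test_planted_gm_reduction_recovered(self):
        """18+18 synthetic GM maps with a ratio-0.8 sphere: the negative-t
        region at voxel p < 0.05 overlaps the planted sphere (Dice > 0.3)."""
        from lfoamp import VolumeGrid, make_group_mask
        from lfoamp.preprocess import gaussian_smooth

        grid = VolumeGrid.default((24, 24, 16))
        eff = PlantedEffect(
            center_mm=(9, 9, 0), radius_mm=9.0, amplitude_ratio=0.8,
            applies_to="gm_volume",
        )
        spec = SyntheticSpec(
            n_per_group=18, grid=grid, n_volumes_acquired=20, effects=(eff,), seed=13
        )
        records = simulate_records(spec)
        gm = {r.subject_id: simulate_gm_map(spec, r) for r in records}
        mask = make_group_mask(list(gm.values()), grid, threshold=0.15)
        smoothed = {k: gaussian_smooth(v, grid, 4.0) for k, v in gm.items()}
        smap = gm_group_difference(
            [smoothed[r.subject_id] for r in records if r.group == "patient"],
            [smoothed[r.subject_id] for r in records if r.group == "control"],
            mask,
            presmoothed=True,
        )
        t_crit = stats.t.ppf(0.975, smap.df)
        detected = (smap.statistic < -t_crit) & mask.include
        planted = eff.member_mask(grid) & mask.include
        dice = 2 * (detected & planted).sum() / (detected.sum() + planted.sum())
        assert dice > 0.3
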