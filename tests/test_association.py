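"""Burden regression, permutation p-values and max-T region tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cnvburden.association import (
    RegionDef,
    burden_regression,
    carrier_ttest,
    maxT_correction,
    permutation_p_regression,
    region_carrier_mask,
    regression_grid,
)


def null_data(n=500, seed=0, n_cohorts=2):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    x = rng.poisson(0.2, size=n).astype(float)
    cohorts = np.array([f"c{i % n_cohorts}" for i in range(n)])
    return y, x, cohorts


class TestBurdenRegression:
    def test_zero_variance_burden_flagged(self):
        y, _, cohorts = null_data()
        res = burden_regression(y, np.zeros_like(y), cohorts)
        assert not res.defined
        assert np.isnan(res.standardized_beta)

    def test_standardized_beta_matches_manual_scaling(self):
        y, x, cohorts = null_data(seed=3)
        res = burden_regression(y, x, cohorts)
        import statsmodels.api as sm

        X = sm.add_constant(
            np.column_stack([x, (cohorts == "c1").astype(float)])
        )
        fit = sm.OLS(y, X).fit()
        manual = fit.params[1] * x.std(ddof=1) / y.std(ddof=1)
        assert res.standardized_beta == pytest.approx(manual, rel=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_duplicating_samples_preserves_standardized_beta(self):
        y, x, cohorts = null_data(seed=5)
        res1 = burden_regression(y, x, cohorts)
        res2 = burden_regression(np.tile(y, 2), np.tile(x, 2), np.tile(cohorts, 2))
        assert res2.standardized_beta == pytest.approx(res1.standardized_beta, rel=1e-10)

    def test_cohort_relabeling_invariance(self):
        y, x, cohorts = null_data(seed=7, n_cohorts=3)
        res1 = burden_regression(y, x, cohorts)
        relabeled = np.char.add("cohort_", cohorts)
        res2 = burden_regression(y, x, relabeled)
        assert res2.standardized_beta == pytest.approx(res1.standardized_beta, rel=1e-12)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-10)


class TestPermutationP:
    def test_same_seed_identical(self):
        y, x, cohorts = null_data(seed=11)
        p1 = permutation_p_regression(y, x, cohorts, n_permutations=500, seed=42)
        p2 = permutation_p_regression(y, x, cohorts, n_permutations=500, seed=42)
        assert p1 == p2

    def test_agrees_with_analytic_p_under_null(self):
        y, x, cohorts = null_data(n=1000, seed=13)
        res = burden_regression(y, x, cohorts)
        B = 1000
        emp = permutation_p_regression(y, x, cohorts, n_permutations=B, seed=1)
        p = res.p_value
        mc_se = np.sqrt(p * (1 - p) / B)
        assert abs(emp - p) < 3 * mc_se + 1 / B

    def test_extreme_observation_gives_zero(self):
        rng = np.random.default_rng(17)
        n = 200
        x = rng.poisson(0.3, size=n).astype(float)
        y = 5 * (x - x.mean()) + 0.01 * rng.normal(size=n)  # overwhelming effect
        emp = permutation_p_regression(y, x, None, n_permutations=200, seed=2)
        assert emp == 0.0
        smoothed = permutation_p_regression(
            y, x, None, n_permutations=200, seed=2, smoothed=True
        )
        assert smoothed == pytest.approx(1 / 201)

    def test_invalid_permutation_count(self):
        y, x, cohorts = null_data()
        with pytest.raises(ValueError):
            permutation_p_regression(y, x, cohorts, n_permutations=0)

    def test_cohort_relabeling_invariance(self):
        y, x, cohorts = null_data(seed=19, n_cohorts=3)
        p1 = permutation_p_regression(y, x, cohorts, n_permutations=300, seed=5)
        p2 = permutation_p_regression(
            y, x, np.char.add("X", cohorts), n_permutations=300, seed=5
        )
        assert p1 == p2


def region_fixture(n=400, carriers=(0, 1, 2, 3), seed=0, shift=0.0):
    """Phenotype table + rare CNVs giving region r{i} carriers[i] carriers."""
    rng = np.random.default_rng(seed)
    sample_ids = np.array([f"s{i:04d}" for i in range(n)])
    y = rng.normal(size=n)
    regions, rows = [], []
    used = set()
    for i, k in enumerate(carriers):
        r = RegionDef(f"r{i}", str(i + 1), 1_000_000, 2_000_000)
        regions.append(r)
        free = [j for j in range(n) if j not in used]
        chosen = rng.choice(free, size=k, replace=False) if k else []
        for j in chosen:
            used.add(j)
            y[j] += shift if i == len(carriers) - 1 else 0.0
            rows.append(
                {
                    "sample_id": sample_ids[j],
                    "chromosome": r.chromosome,
                    "start_bp": 1_500_000,
                    "end_bp": 2_500_000,
                    "dosage_class": "deletion",
                    "length_bp": 1_000_001,
                }
            )
    cnvs = pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "dosage_class", "length_bp"],
    )
    pheno = pd.DataFrame({"sample_id": sample_ids, "gf_residual": y})
    return regions, cnvs, pheno


class TestCarrierTtest:
    def test_two_carriers_not_tested(self):
        regions, cnvs, pheno = region_fixture(carriers=(2,))
        res = carrier_ttest(regions[0], cnvs, pheno)
        assert not res.tested
        assert res.n_carriers == 2

    def test_matches_scipy_closed_form(self):
        regions, cnvs, pheno = region_fixture(carriers=(5,), seed=3)
        res = carrier_ttest(regions[0], cnvs, pheno)
        mask = region_carrier_mask(regions[0], cnvs, pheno["sample_id"].to_numpy())
        y = pheno["gf_residual"].to_numpy()
        expected = scipy.stats.ttest_ind(y[mask], y[~mask], equal_var=True)
        assert res.t_statistic == pytest.approx(float(expected.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(expected.pvalue), rel=1e-12)
        welch = carrier_ttest(regions[0], cnvs, pheno, equal_var=False)
        expected_w = scipy.stats.ttest_ind(y[mask], y[~mask], equal_var=False)
        assert welch.t_statistic == pytest.approx(float(expected_w.statistic), rel=1e-12)

    def test_degenerate_variance_flagged(self):
        regions, cnvs, pheno = region_fixture(carriers=(4,), seed=5)
        pheno["gf_residual"] = 1.0
        res = carrier_ttest(regions[0], cnvs, pheno)
        assert res.tested
        assert np.isnan(res.t_statistic)

    def test_any_overlap_defines_carrier(self):
        region = RegionDef("r", "1", 1_000_000, 2_000_000)
        cnvs = pd.DataFrame(
            [
                {"sample_id": "a", "chromosome": "1", "start_bp": 1_999_999, "end_bp": 3_000_000},
                {"sample_id": "b", "chromosome": "1", "start_bp": 2_000_001, "end_bp": 3_000_000},
                {"sample_id": "c", "chromosome": "2", "start_bp": 1_000_000, "end_bp": 2_000_000},
            ]
        )
        mask = region_carrier_mask(region, cnvs, np.array(["a", "b", "c"]))
        assert mask.tolist() == [True, False, False]


class TestMaxT:
    def test_single_region_equals_single_test_permutation(self):
        """Degenerate panel: maxT reduces to one region's own permutation p."""
        regions, cnvs, pheno = region_fixture(carriers=(4,), seed=7, shift=-1.5)
        out = maxT_correction(regions, cnvs, pheno, n_permutations=500, seed=9)
        emp = out.loc[0, "empirical_p"]
        # independent simple permutation of the same statistic
        y = pheno["gf_residual"].to_numpy()
        mask = region_carrier_mask(regions[0], cnvs, pheno["sample_id"].to_numpy())
        t_obs = abs(scipy.stats.ttest_ind(y[mask], y[~mask], equal_var=True).statistic)
        rng = np.random.default_rng(10)
        exceed = 0
        B = 500
        for _ in range(B):
            yp = rng.permutation(y)
            t = abs(scipy.stats.ttest_ind(yp[mask], yp[~mask], equal_var=True).statistic)
            exceed += t > t_obs
        assert abs(emp - exceed / B) < 3 * np.sqrt(max(emp, 0.01) * 0.99 / B) + 0.02

    def test_max_dominates_single_region_p(self):
        regions, cnvs, pheno = region_fixture(carriers=(3, 4, 5, 6), seed=11, shift=-1.0)
        panel = maxT_correction(regions, cnvs, pheno, n_permutations=400, seed=12)
        for r in regions:
            single = maxT_correction([r], cnvs, pheno, n_permutations=400, seed=12)
            e_panel = panel.loc[panel.region_id == r.region_id, "empirical_p"].iloc[0]
            e_single = single.loc[0, "empirical_p"]
            assert e_panel >= e_single  # same permutation stream, max dominates

    def test_adding_region_never_decreases_empirical_p(self):
        regions, cnvs, pheno = region_fixture(carriers=(3, 4, 5), seed=13, shift=-1.0)
        small = maxT_correction(regions[:2], cnvs, pheno, n_permutations=400, seed=14)
        big = maxT_correction(regions, cnvs, pheno, n_permutations=400, seed=14)
        for rid in ("r0", "r1"):
            e_small = small.loc[small.region_id == rid, "empirical_p"].iloc[0]
            e_big = big.loc[big.region_id == rid, "empirical_p"].iloc[0]
            if np.isfinite(e_small):
                assert e_big >= e_small

    def test_untestable_regions_excluded_and_warned(self):
        regions, cnvs, pheno = region_fixture(carriers=(1, 2), seed=15)
        with pytest.warns(UserWarning, match="no testable regions"):
            out = maxT_correction(regions, cnvs, pheno, n_permutations=100, seed=16)
        assert (~out["tested"]).all()
        assert out["empirical_p"].isna().all()

    def test_deterministic_under_seed(self):
        regions, cnvs, pheno = region_fixture(carriers=(3, 5), seed=17)
        a = maxT_correction(regions, cnvs, pheno, n_permutations=300, seed=18)
        b = maxT_correction(regions, cnvs, pheno, n_permutations=300, seed=18)
        pd.testing.assert_frame_equal(a, b)


class TestRegressionGrid:
    def test_grid_shape_and_determinism(self):
        rng = np.random.default_rng(21)
        n = 300
        counts = rng.poisson(0.3, size=n)
        burden = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "cohort": np.repeat(["c1", "c2"], n // 2),
                "count_all": counts,
                "count_del": counts // 2,
                "count_dup": counts - counts // 2,
                "length_all": counts * 600_000,
                "length_del": (counts // 2) * 600_000,
                "length_dup": (counts - counts // 2) * 600_000,
                "genes_all": counts,
                "genes_del": counts // 2,
                "genes_dup": counts - counts // 2,
            }
        )
        derived = pd.DataFrame(
            {
                "sample_id": burden["sample_id"],
                "gf_residual": rng.normal(size=n),
                "gc_residual": rng.normal(size=n),
            }
        )
        g1 = regression_grid(burden, derived, n_permutations=100, seed=3)
        g2 = regression_grid(burden, derived, n_permutations=100, seed=3)
        pd.testing.assert_frame_equal(g1, g2)
        assert len(g1) == 18
        assert set(g1.phenotype) == {"g_f", "g_c"}
        assert g1["empirical_p"].between(0, 1).all()
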