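"""Permutation inference, multiple-testing control, correlations, power."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from scnkit import (
    DensitySweep,
    cohort_stats,
    fdr_bh,
    partial_correlation,
    permutation_test,
    run_group_comparison,
    t_from_summary,
    two_sample_power,
)
from scnkit.inference import results_table


class TestFdrBH:
    def test_hand_executed_step_up(self):
        # thresholds (i/m)q: 0.0125, 0.025, 0.0375, 0.05 -> first three pass
        reject, p_adj = fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert reject.tolist() == [True, True, True, False]
        np.testing.assert_allclose(p_adj[:3], [0.04, 0.04, 0.04])

    def test_all_ones_reject_nothing(self):
        reject, p_adj = fdr_bh([1.0] * 6)
        assert not reject.any()
        assert (p_adj == 1.0).all()

    def test_single_p_is_identity(self):
        reject, p_adj = fdr_bh([0.04], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_adjusted_dominates_raw_and_bonferroni_is_subset(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.2, 40)
        reject, p_adj = fdr_bh(p, q=0.05)
        assert (p_adj >= p - 1e-15).all()
        bonf = p < 0.05 / len(p)
        assert (reject | ~bonf).all()  # BH rejects wherever Bonferroni does


class TestPartialCorrelation:
    def test_orthogonal_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        # orthogonalize z against x, y and the intercept
        Q = np.column_stack([np.ones(n), x, y])
        z = z - Q @ np.linalg.lstsq(Q, z, rcond=None)[0]
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_identical_variables_correlate_at_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        z = rng.normal(size=(30, 2))
        res = partial_correlation(x, x.copy(), z)
        assert res.r == pytest.approx(1.0)

    def test_recovers_planted_partial_correlation_despite_confounder(self):
        rng = np.random.default_rng(5)
        n, rho = 400, 0.4
        c = rng.normal(size=n)  # confounder drives both
        ex = rng.normal(size=n)
        ey = rng.normal(size=n)
        x = c + ex
        # after removing c, corr(x_res, y_res) targets rho by construction
        y = c + rho * ex + np.sqrt(1 - rho**2) * ey
        res = partial_correlation(x, y, c)
        assert res.r == pytest.approx(rho, abs=2 / np.sqrt(n))

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 80
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "z1": rng.normal(size=n),
                "z2": rng.normal(size=n),
            }
        )
        df["y"] += 0.4 * df["x"] + 0.3 * df["z1"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(df["x"], df["y"], df[["z1", "z2"]])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_constant_after_residualization_rejected(self):
        n = 30
        z = np.linspace(0, 1, n)
        x = 2.0 + 3.0 * z  # exact function of the covariate
        y = np.random.default_rng(7).normal(size=n)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, y, z)

    def test_bonferroni_factor(self):
        rng = np.random.default_rng(8)
        x, y, z = rng.normal(size=(3, 50))
        res = partial_correlation(x, y, z, m_tests=10)
        assert res.p_bonf == pytest.approx(min(1.0, res.p * 10))


class TestCohortStats:
    def test_identical_groups_give_t_zero_p_one(self, atlas20):
        rng = np.random.default_rng(9)
        vals = rng.normal(50, 5, 15)
        cov = pd.DataFrame(
            {
                "age": np.r_[vals, vals],
                "sex": np.tile([0, 1], 15),
                "tiv": rng.normal(1.4e6, 1e5, 30),
            }
        )
        thick = rng.uniform(2, 3, (30, 20))
        ds = make_dataset(thick, atlas20, ["a"] * 15 + ["b"] * 15, rng, cov)
        row = cohort_stats(ds, ["age"]).iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_sex_chi_square_without_continuity_correction(self, atlas20):
        # 42 male / 14 female vs 37 male / 22 female -> Pearson chi2 = 2.017
        rng = np.random.default_rng(10)
        sex = np.r_[np.ones(42), np.zeros(14), np.ones(37), np.zeros(22)].astype(int)
        cov = pd.DataFrame(
            {"age": rng.uniform(45, 70, 115), "sex": sex,
             "tiv": rng.normal(1.4e6, 1e5, 115)}
        )
        thick = rng.uniform(2, 3, (115, 20))
        ds = make_dataset(
            thick, atlas20, ["patient"] * 56 + ["control"] * 59, rng, cov
        )
        row = cohort_stats(ds, ["sex"]).iloc[0]
        assert row["test"] == "chi2"
        assert row["statistic"] == pytest.approx(2.0173, abs=1e-3)

    def test_skewed_variable_uses_mann_whitney(self, atlas20):
        rng = np.random.default_rng(11)
        cov = pd.DataFrame(
            {
                "age": rng.uniform(45, 70, 40),
                "sex": rng.integers(0, 2, 40),
                "tiv": rng.normal(1.4e6, 1e5, 40),
                "hba1c": np.exp(rng.normal(1.5, 1.0, 40)),  # strongly skewed
            }
        )
        thick = rng.uniform(2, 3, (40, 20))
        ds = make_dataset(thick, atlas20, ["a"] * 20 + ["b"] * 20, rng, cov)
        row = cohort_stats(ds, ["hba1c"]).iloc[0]
        assert row["test"] == "mannwhitney"

    def test_summary_statistics_t_for_printed_group_summaries(self):
        # pooled-variance t from means±SD of a glucose comparison
        t, df, p = t_from_summary(8.32, 3.13, 56, 4.10, 2.06, 59)
        assert t == pytest.approx(8.582, abs=1e-3)
        assert df == 113
        assert p < 1e-10


class TestTwoSamplePower:
    def test_reported_design_power(self):
        assert two_sample_power(0.56, 56, 59, 0.05) == pytest.approx(0.85, abs=0.005)

    def test_null_effect_gives_alpha(self):
        assert two_sample_power(0.0, 56, 59, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_saturates(self):
        assert two_sample_power(3.0, 56, 59, 0.05) > 0.999

    @pytest.mark.parametrize("kwargs", [
        {"d": -0.5, "n1": 10, "n2": 10},
        {"d": 0.5, "n1": 1, "n2": 10},
        {"d": 0.5, "n1": 10, "n2": 10, "alpha": 0.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            two_sample_power(**kwargs)


class TestPermutationTest:
    def test_identical_group_matrices_give_p_one(self, atlas20):
        rng = np.random.default_rng(12)
        half = rng.uniform(2, 3, (10, 20))
        thick = np.vstack([half, half])  # group b duplicates group a exactly
        cov_half = pd.DataFrame(
            {"age": rng.uniform(45, 70, 10), "sex": rng.integers(0, 2, 10),
             "tiv": rng.normal(1.4e6, 1e5, 10)}
        )
        cov = pd.concat([cov_half, cov_half], ignore_index=True)
        ds = make_dataset(thick, atlas20, ["a"] * 10 + ["b"] * 10, rng, cov)
        res = permutation_test(
            ds, "C", sweep=DensitySweep(0.2, 0.3, 0.05), n_perm=20, seed=1
        )
        assert res.observed_diff == 0.0
        assert res.p == 1.0

    def test_results_deterministic_under_seed(self, small_cohort):
        sweep = DensitySweep(0.15, 0.35, 0.05)
        a = permutation_test(small_cohort, "C", sweep=sweep, n_perm=30, seed=3)
        b = permutation_test(small_cohort, "C", sweep=sweep, n_perm=30, seed=3)
        assert a.observed_diff == b.observed_diff
        assert a.p == b.p

    def test_p_never_zero_and_bounded(self, small_cohort):
        res = permutation_test(
            small_cohort, "Eglobal", sweep=DensitySweep(0.2, 0.3, 0.05),
            n_perm=24, seed=4,
        )
        assert 1.0 / 25 <= res.p <= 1.0

    def test_nodal_scope_returns_fdr_per_region(self, small_cohort):
        results = permutation_test(
            small_cohort, "DC", scope="nodal",
            sweep=DensitySweep(0.2, 0.3, 0.05), n_perm=20, seed=5,
        )
        assert len(results) == small_cohort.n_regions
        for r in results:
            assert r.scope.startswith("node:")
            assert r.p_fdr is not None and r.p_fdr >= r.p - 1e-15
        table = results_table(results)
        assert set(table["region_id"]) == set(small_cohort.atlas.region_id)

    def test_strong_effect_detected_in_expected_direction(self, small_cohort):
        """Patients have lower within-module loading; clustering AUC should
        come out lower in patients with a small p."""
        res = permutation_test(
            small_cohort, "C", sweep=DensitySweep(0.15, 0.35, 0.05),
            n_perm=99, seed=6,
        )
        assert res.observed_diff < 0
        assert res.p < 0.05

    def test_invalid_metric_and_nperm_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown metric"):
            run_group_comparison(small_cohort, metrics="Q", n_perm=5)
        with pytest.raises(ValueError, match="n_perm"):
            run_group_comparison(small_cohort, metrics="C", n_perm=0)
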