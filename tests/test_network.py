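"""Residualization, correlation networks, and density thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnkit import (
    DensitySweep,
    build_scn,
    check_density_validity,
    residualize,
    threshold_stack,
)
from scnkit.network import CovarianceNetwork, edge_count_at, rank_edges

from conftest import make_dataset


class TestDensitySweep:
    def test_default_sweep_has_31_points(self):
        d = DensitySweep().densities
        assert len(d) == 31
        assert d[0] == pytest.approx(0.10)
        assert d[-1] == pytest.approx(0.40)

    @pytest.mark.parametrize(
        "kwargs", [{"d_min": 0.4, "d_max": 0.1}, {"d_min": 0.0}, {"step": 0.0},
                   {"d_max": 1.0}]
    )
    def test_invalid_sweeps_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DensitySweep(**{"d_min": 0.1, "d_max": 0.4, "step": 0.01, **kwargs})


class TestResidualize:
    def test_exact_linear_covariate_recovery(self, atlas20):
        """Thickness built as an exact linear function of age leaves zero
        residuals (up to least-squares numerics)."""
        rng = np.random.default_rng(8)
        n = 24
        age = rng.uniform(45, 70, n)
        thick = 2.0 + 0.01 * age[:, None] * np.ones((n, 20))
        cov = pd.DataFrame(
            {"age": age, "sex": rng.integers(0, 2, n),
             "tiv": rng.normal(1.4e6, 1e5, n)}
        )
        ds = make_dataset(thick, atlas20, ["a"] * 12 + ["b"] * 12, rng, cov)
        resid = residualize(ds)
        for r in resid.values():
            np.testing.assert_allclose(r, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_covariates(self, small_cohort):
        resid = residualize(small_cohort)
        for label in small_cohort.group_order:
            mask = small_cohort.group_mask(label)
            for name in ("age", "sex", "tiv"):
                z = small_cohort.covariates.loc[mask, name].to_numpy(float)
                dots = z @ resid[label] / len(z)
                scale = np.abs(z).mean() or 1.0
                np.testing.assert_allclose(dots / scale, 0.0, atol=1e-8)

    def test_constant_covariates_reduce_to_mean_centering(self, atlas20):
        rng = np.random.default_rng(9)
        n = 20
        thick = rng.uniform(2, 3, (n, 20))
        cov = pd.DataFrame(
            {"age": np.full(n, 55.0), "sex": rng.integers(0, 2, n),
             "tiv": rng.normal(1.4e6, 1e5, n), "noise_cov": rng.normal(size=n)}
        )
        ds = make_dataset(thick, atlas20, ["a"] * 10 + ["b"] * 10, rng, cov)
        resid = residualize(ds, covariate_names=())
        for label in ("a", "b"):
            mask = ds.group_mask(label)
            centered = thick[mask] - thick[mask].mean(axis=0)
            np.testing.assert_allclose(resid[label], centered, atol=1e-10)

    def test_single_sex_group_names_offending_covariate(self, atlas20):
        rng = np.random.default_rng(10)
        n = 16
        thick = rng.uniform(2, 3, (n, 20))
        cov = pd.DataFrame(
            {"age": rng.uniform(45, 70, n), "sex": np.zeros(n, dtype=int),
             "tiv": rng.normal(1.4e6, 1e5, n)}
        )
        ds = make_dataset(thick, atlas20, ["a"] * 8 + ["b"] * 8, rng, cov)
        with pytest.raises(ValueError, match="sex"):
            residualize(ds)

    def test_pooled_scope_differs_from_per_group(self, small_cohort):
        per = residualize(small_cohort, scope="per-group")
        pooled = residualize(small_cohort, scope="pooled")
        assert not np.allclose(per["patient"], pooled["patient"])


class TestBuildScn:
    def test_identical_regions_correlate_at_one(self, atlas20):
        rng = np.random.default_rng(11)
        base = rng.normal(size=30)
        resid = rng.normal(size=(30, 20))
        resid[:, 3] = base
        resid[:, 7] = base
        net = build_scn(resid, "g")
        assert net.corr[3, 7] == pytest.approx(1.0)

    def test_symmetry_exact_and_zero_diagonal(self):
        rng = np.random.default_rng(12)
        net = build_scn(rng.normal(size=(56, 30)), "g")
        assert (net.corr == net.corr.T).all()
        assert (np.diag(net.corr) == 0).all()

    def test_null_correlations_within_sampling_bound(self):
        rng = np.random.default_rng(13)
        n = 56
        net = build_scn(rng.normal(size=(n, 40)), "g")
        off = net.corr[np.triu_indices(40, k=1)]
        assert abs(off.mean()) < 3.0 / np.sqrt(n - 1)

    def test_zero_variance_region_yields_zero_correlations(self):
        rng = np.random.default_rng(14)
        resid = rng.normal(size=(20, 10))
        resid[:, 5] = 1.7
        net = build_scn(resid, "g")
        assert np.all(net.corr[5] == 0)
        assert np.all(np.isfinite(net.corr))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            build_scn(np.random.default_rng(0).normal(size=(3, 10)), "g")


class TestThresholdStack:
    def test_top_k_edges_match_hand_ranking(self):
        # 4 nodes, 6 distinct pair correlations; K=3 keeps the top three
        corr = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1,
                (1, 2): 0.7, (1, 3): 0.3, (2, 3): -0.5}
        for (i, j), v in vals.items():
            corr[i, j] = corr[j, i] = v
        net = CovarianceNetwork("g", corr, ())
        sweep = DensitySweep(d_min=0.5, d_max=0.5, step=0.01)  # K = round(3) = 3
        stack = threshold_stack(net, sweep)
        A = stack.adj[0]
        expected = {(0, 1), (0, 2), (1, 2)}
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(A, 1)))}
        assert got == expected

    def test_full_density_gives_complete_graph(self):
        rng = np.random.default_rng(15)
        corr = np.corrcoef(rng.normal(size=(12, 8)), rowvar=False)
        np.fill_diagonal(corr, 0)
        net = CovarianceNetwork("g", corr, ())
        stack = threshold_stack(net, DensitySweep(d_min=0.99, d_max=0.99))
        A = stack.adj[0]
        assert A.sum() == 8 * 7  # complete graph, both triangle halves

    def test_tied_values_resolve_lexicographically_and_deterministically(self):
        corr = np.zeros((5, 5))
        iu = np.triu_indices(5, k=1)
        corr[iu] = 0.5  # every pair tied
        corr = corr + corr.T
        net = CovarianceNetwork("g", corr, ())
        sweep = DensitySweep(d_min=0.3, d_max=0.3)  # K = 3 of 10
        a1 = threshold_stack(net, sweep).adj[0]
        a2 = threshold_stack(net, sweep).adj[0]
        assert (a1 == a2).all()
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(a1, 1)))}
        assert got == {(0, 1), (0, 2), (0, 3)}  # first pairs in (i, j) order

    def test_edge_counts_exact_and_nested_for_random_network(self):
        rng = np.random.default_rng(16)
        corr = np.corrcoef(rng.normal(size=(60, 50)), rowvar=False)
        np.fill_diagonal(corr, 0)
        stack = threshold_stack(CovarianceNetwork("g", corr, ()), DensitySweep())
        counts = stack.edge_counts()
        expected = [edge_count_at(d, 50) for d in stack.densities]
        assert list(counts) == expected
        for k in range(len(stack) - 1):
            assert not (stack.adj[k] & ~stack.adj[k + 1]).any()

    def test_degenerate_density_rejected(self):
        corr = np.zeros((10, 10))
        with pytest.raises(ValueError, match="< 1 edge"):
            threshold_stack(
                CovarianceNetwork("g", corr, ()),
                DensitySweep(d_min=0.001, d_max=0.002, step=0.001),
            )

    def test_absolute_ranking_includes_strong_negative_edges(self):
        corr = np.zeros((4, 4))
        corr[0, 1] = corr[1, 0] = -0.95
        corr[2, 3] = corr[3, 2] = 0.5
        net = CovarianceNetwork("g", corr, ())
        sweep = DensitySweep(d_min=0.17, d_max=0.17)  # K = 1
        signed = threshold_stack(net, sweep, "signed").adj[0]
        absolute = threshold_stack(net, sweep, "absolute").adj[0]
        assert signed[2, 3] and not signed[0, 1]
        assert absolute[0, 1] and not absolute[2, 3]


class TestDensityValidity:
    def test_default_sweep_on_148_nodes_not_fragmented_at_low_end(self, default_cohort):
        resid = residualize(default_cohort)
        net = build_scn(resid["patient"], "patient")
        report = check_density_validity(threshold_stack(net))
        first = report.iloc[0]
        assert first["n_edges"] == round(0.10 * 148 * 147 / 2) == 1088
        assert not first["fragmented"]

    def test_sparse_small_graph_flagged_fragmented(self):
        rng = np.random.default_rng(17)
        corr = np.corrcoef(rng.normal(size=(20, 10)), rowvar=False)
        np.fill_diagonal(corr, 0)
        stack = threshold_stack(
            CovarianceNetwork("g", corr, ()), DensitySweep(d_min=0.03, d_max=0.03)
        )
        report = check_density_validity(stack)
        assert report.iloc[0]["n_edges"] == 1
        assert report.iloc[0]["fragmented"]

    def test_component_count_monotone_in_density(self):
        rng = np.random.default_rng(18)
        corr = np.corrcoef(rng.normal(size=(40, 30)), rowvar=False)
        np.fill_diagonal(corr, 0)
        stack = threshold_stack(CovarianceNetwork("g", corr, ()), DensitySweep())
        comps = check_density_validity(stack)["n_components"].to_numpy()
        assert (np.diff(comps) <= 0).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(6, 24))
def test_edge_ranking_is_a_permutation_of_all_pairs(seed, n):
    rng = np.random.default_rng(seed)
    corr = np.corrcoef(rng.normal(size=(n + 5, n)), rowvar=False)
    np.fill_diagonal(corr, 0)
    ranked = rank_edges(corr)
    assert len(ranked) == n * (n - 1) // 2
    assert len({(i, j) for i, j in ranked}) == len(ranked)
    vals = corr[ranked[:, 0], ranked[:, 1]]
    assert (np.diff(vals) <= 1e-15).all()
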