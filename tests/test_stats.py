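"""Per-edge OLS, M_eff correction, cluster shifts and summary tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conndiff.atlas import build_edge_index
from conndiff.stats import (
    CohortStack,
    StackError,
    adjusted_threshold,
    chi2_2x2,
    cluster_shift_tests,
    edge_regression,
    effective_number_of_tests,
    group_mean_networks,
    handle_missing,
    li_ji_meff,
    welch_from_summary,
)


def _stack(X, group, covariates=None, kind="DMC"):
    X = np.asarray(X, dtype=float)
    M, n = X.shape
    r = 2
    while r * (r - 1) // 2 < M:
        r += 1
    idx = build_edge_index(r)
    full = np.full((idx.n_edges, n), 0.0)
    full[:M] = X
    rng = np.random.default_rng(0)
    full[M:] = rng.normal(size=(idx.n_edges - M, n))
    subj = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "group": group}
    )
    if covariates:
        for k, v in covariates.items():
            subj[k] = v
    return CohortStack(kind, full, subj, idx)


class TestEdgeRegression:
    def test_identical_groups_give_null_stats(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        stack = _stack(vals[None, :], [0, 0, 0, 1, 1, 1])
        res = edge_regression(stack)
        assert res.t[0] == pytest.approx(0.0, abs=1e-10)
        assert res.p[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_pooled_two_sample_t(self):
        stack = _stack(
            np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]), [0, 0, 0, 1, 1, 1]
        )
        res = edge_regression(stack)
        assert res.t[0] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-10)
        assert res.df[0] == 4
        assert res.p[0] == pytest.approx(0.0213, abs=5e-4)
        assert res.beta[0] == pytest.approx(3.0)
        # positive t means group 1 > group 0
        assert res.t[0] > 0

    def test_collinear_covariate_masks_all_edges(self):
        g = [0, 0, 0, 1, 1, 1]
        stack = _stack(
            np.random.default_rng(1).normal(size=(2, 6)),
            g,
            covariates={"copy": list(map(float, g))},
        )
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            res = edge_regression(stack, ["copy"])
        assert np.isnan(res.t).all() and np.isnan(res.p).all()

    def test_unknown_covariate_rejected(self):
        stack = _stack(np.zeros((1, 6)), [0, 0, 0, 1, 1, 1])
        with pytest.raises(StackError, match="unknown covariate"):
            edge_regression(stack, ["age"])

    def test_matches_statsmodels_with_covariate(self, rng):
        import statsmodels.api as sm

        n = 24
        g = np.repeat([0, 1], n // 2)
        age = rng.normal(50, 8, n)
        X = rng.normal(size=(3, n)) + 0.8 * g + 0.05 * age
        stack = _stack(X, g, covariates={"age": age})
        res = edge_regression(stack, ["age"])
        A = sm.add_constant(np.column_stack([g, age]))
        for e in range(3):
            fit = sm.OLS(X[e], A).fit()
            assert res.beta[e] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.t[e] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.p[e] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_missing_values_listwise_per_edge(self):
        X = np.array([[1.0, np.nan, 3.0, 4.0, 5.0, 6.0], [1, 2, 3, 4, 5, 6.0]])
        stack = _stack(X, [0, 0, 0, 1, 1, 1])
        res = edge_regression(stack)
        assert res.n_used[0] == 5
        assert res.n_used[1] == 6


class TestGroupMeans:
    def test_single_subject_per_group(self):
        X = np.array([[2.0, 7.0]])
        # need n>=4: pad groups
        X = np.array([[2.0, 2.0, 7.0, 7.0]])
        stack = _stack(X, [0, 0, 1, 1])
        g0, g1 = group_mean_networks(stack)
        i, j = stack.edge_index.pair_of(0)
        assert g0.weights[i, j] == 2.0
        assert g1.weights[i, j] == 7.0

    def test_mean_with_one_masked_entry(self):
        X = np.array([[1.0, np.nan, 3.0, 5.0]])
        stack = _stack(X, [0, 0, 0, 1])
        g0, _ = group_mean_networks(stack)
        i, j = stack.edge_index.pair_of(0)
        assert g0.weights[i, j] == pytest.approx(2.0)  # mean of {1, 3}

    def test_edge_missing_for_whole_group_masked(self):
        X = np.array([[np.nan, np.nan, 3.0, 5.0]])
        stack = _stack(X, [0, 0, 1, 1])
        g0, g1 = group_mean_networks(stack)
        i, j = stack.edge_index.pair_of(0)
        assert np.isnan(g0.weights[i, j])
        assert g1.weights[i, j] == 4.0


class TestMeff:
    @pytest.mark.parametrize(
        "eigs, expected",
        [
            ([3, 0, 0], 1.0),
            ([1, 1, 1], 3.0),
            ([1.5, 0.5], 2.0),
            ([1.0], 1.0),
            ([2.0, 0.0], 1.0),
        ],
    )
    def test_eigenvalue_rule(self, eigs, expected):
        assert li_ji_meff(eigs) == pytest.approx(expected)

    def test_single_edge_meff_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        idx = build_edge_index(2)
        subj = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)],
             "group": np.repeat([0, 1], 6)}
        )
        two = CohortStack("DMC", x[None, :], subj, idx)
        assert effective_number_of_tests(two) == pytest.approx(1.0)

    def test_identical_pair_of_edges_meff_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        idx = build_edge_index(3)  # 3 edges
        X = np.vstack([x, x, x])
        subj = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)],
             "group": np.repeat([0, 1], 5)}
        )
        stack = CohortStack("DMC", X, subj, idx)
        assert effective_number_of_tests(stack) == pytest.approx(1.0)

    def test_gram_form_matches_direct_eigendecomposition(self, rng):
        # M > n forces the n x n Gram route; compare with the M x M route
        n, M = 8, 15
        X = rng.normal(size=(M, n))
        idx = build_edge_index(6)  # 15 edges
        subj = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)],
             "group": np.repeat([0, 1], n // 2)}
        )
        stack = CohortStack("DMC", X, subj, idx)
        via_gram = effective_number_of_tests(stack)
        Z = X - X.mean(axis=1, keepdims=True)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        direct = li_ji_meff(np.linalg.eigvalsh(Z @ Z.T))
        assert via_gram == pytest.approx(direct, abs=1e-8)

    def test_meff_bounded_by_rank(self, rng):
        n = 10
        idx = build_edge_index(12)
        X = rng.normal(size=(idx.n_edges, n))
        subj = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)],
             "group": np.repeat([0, 1], n // 2)}
        )
        m_eff = effective_number_of_tests(
            CohortStack("DMC", X, subj, idx)
        )
        # rank <= n-1 nonzero eigenvalues, each contributing f(lam) < 2
        assert 1.0 <= m_eff <= min(idx.n_edges, 2 * (n - 1))
        assert m_eff <= idx.n_edges

    def test_constant_edge_raises(self):
        idx = build_edge_index(2)
        X = np.full((1, 6), 3.14)
        subj = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(6)],
             "group": [0, 0, 0, 1, 1, 1]}
        )
        with pytest.raises(StackError, match="constant"):
            effective_number_of_tests(CohortStack("DMC", X, subj, idx))


class TestAdjustedThreshold:
    def test_no_correction_limit(self):
        c = adjusted_threshold(0.05, 1.0)
        assert c.alpha_adj == 0.05 and c.s == pytest.approx(1.0)

    def test_meff_100(self):
        c = adjusted_threshold(0.05, 100.0)
        assert c.alpha_adj == pytest.approx(5e-4)
        assert c.s == pytest.approx(0.3941, abs=5e-5)

    def test_threshold_decreasing_in_meff(self):
        vals = [adjusted_threshold(0.05, m).alpha_adj for m in (1, 2, 10, 400)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_reference_line_identity(self):
        # -log10(alpha_adj) * s == -log10(alpha): the purpose of s
        for m in (1.0, 3.7, 435.0):
            c = adjusted_threshold(0.05, m)
            assert -np.log10(c.alpha_adj) * c.s == pytest.approx(
                -np.log10(0.05), abs=1e-12
            )

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            adjusted_threshold(alpha, 10.0)


class TestClusterShift:
    def test_symmetric_values_give_null(self):
        df = cluster_shift_tests(
            np.array([-1.0, 1.0]), np.array(["A/A", "A/A"], dtype=object)
        )
        assert df["shift_t"].iloc[0] == pytest.approx(0.0)
        assert df["shift_p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_one_sample_t(self):
        df = cluster_shift_tests(
            np.array([2.0, 1.0, 3.0, 2.0]),
            np.array(["Fro/Temp"] * 4, dtype=object),
        )
        row = df.iloc[0]
        assert row["mean_t"] == pytest.approx(2.0)
        assert row["shift_t"] == pytest.approx(4.899, abs=1e-3)
        assert row["shift_p"] == pytest.approx(0.0163, abs=2e-4)
        assert row["n_edges"] == 4

    def test_zero_variance_cluster_masked(self):
        with pytest.warns(RuntimeWarning, match="zero variance|<2 usable"):
            df = cluster_shift_tests(
                np.array([2.0, 2.0, 2.0]), np.array(["A/A"] * 3, dtype=object)
            )
        assert np.isnan(df["shift_p"].iloc[0])

    def test_single_edge_cluster_masked(self):
        with pytest.warns(RuntimeWarning):
            df = cluster_shift_tests(
                np.array([2.0]), np.array(["A/B"], dtype=object)
            )
        assert np.isnan(df["shift_t"].iloc[0])


class TestHandleMissing:
    def test_identity_when_complete(self, rng):
        X = rng.normal(size=(3, 8))
        stack = _stack(X, np.repeat([0, 1], 4))
        for policy in ("exclude", "impute_group_mean"):
            out = handle_missing(stack, policy)
            np.testing.assert_array_equal(out.X, stack.X)

    def test_impute_group_mean_value(self):
        X = np.array([[1.0, np.nan, 3.0, 9.0]])
        stack = _stack(X, [0, 0, 0, 1])
        out = handle_missing(stack, "impute_group_mean")
        assert out.X[0, 1] == pytest.approx(2.0)

    def test_impute_whole_group_missing_stays_masked(self):
        X = np.array([[np.nan, np.nan, 3.0, 9.0]])
        stack = _stack(X, [0, 0, 1, 1])
        out = handle_missing(stack, "impute_group_mean")
        assert np.isnan(out.X[0, :2]).all()

    def test_exclude_reduces_n_used(self):
        X = np.array([[1.0, np.nan, 3.0, 4.0, 5.0, 6.0]])
        stack = _stack(X, [0, 0, 0, 1, 1, 1])
        res = edge_regression(handle_missing(stack, "exclude"))
        assert res.n_used[0] == 5

    def test_unknown_policy_rejected(self):
        stack = _stack(np.zeros((1, 4)), [0, 0, 1, 1])
        with pytest.raises(ValueError):
            handle_missing(stack, "drop")


class TestSummaryTests:
    def test_welch_identical_summaries_null(self):
        t, df, p = welch_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_age_comparison_rounds_to_printed_value(self):
        # patients 34.8 +/- 9.8 (n=23) vs controls 38.7 +/- 8.7 (n=21)
        _, _, p = welch_from_summary(34.8, 9.8, 23, 38.7, 8.7, 21)
        assert round(p, 1) == 0.2

    def test_welch_education_below_printed_bound(self):
        _, _, p = welch_from_summary(11.5, 2.2, 23, 15.9, 2.0, 20)
        assert p < 0.0001

    def test_welch_satterthwaite_df(self):
        t, df, p = welch_from_summary(0.0, 1.0, 10, 1.0, 2.0, 20)
        # df from the Welch-Satterthwaite formula, between min(n)-1 and n-2
        assert 9 <= df <= 28
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_welch_invalid_sd_rejected(self, bad):
        with pytest.raises(ValueError):
            welch_from_summary(0, bad[0], 10, 1, bad[1], 10)

    def test_chi2_identical_rows_null(self):
        stat, p = chi2_2x2(13, 24, 13, 24)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_hand_computed(self):
        stat, p = chi2_2x2(17, 6, 12, 9)
        assert stat == pytest.approx(1.373, abs=2e-3)

    def test_chi2_scales_with_counts(self):
        s1, _ = chi2_2x2(17, 6, 12, 9)
        s2, _ = chi2_2x2(34, 12, 24, 18)
        assert s2 == pytest.approx(2 * s1, rel=1e-10)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)
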