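"""Mixed-model estimation, Holm correction, correlations, bias checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnalert.ranking import (RankingError, bias_checks, fit_random_intercept_lmm,
                               holm_adjust, rank_parameters, spearman)


def simulate_lmm_data(rng, G, n_per, beta=(70.0, -2.5, 0.5), s_u=3.0, s_e=2.0):
    n = G * n_per
    groups = np.repeat(np.arange(G), n_per)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = X @ np.asarray(beta) + rng.normal(0, s_u, G)[groups] + rng.normal(0, s_e, n)
    return y, X, groups


class TestLMM:
    def test_zero_group_variance_reduces_to_ols(self):
        """Groups with identical response patterns force sigma2_u to 0."""
        n_per, G = 6, 5
        x = np.tile(np.arange(n_per, dtype=float), G)
        y = 2.0 + 0.5 * x + np.tile([0.3, -0.2, 0.1, -0.4, 0.25, -0.05], G)
        X = np.column_stack([np.ones(G * n_per), x])
        groups = np.repeat(np.arange(G), n_per)
        fit = fit_random_intercept_lmm(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.sigma2_u == 0.0
        assert np.allclose(fit.beta, ols, atol=1e-6)
        assert fit.df == len(y) - 2  # OLS limit
        assert fit.df_flag == "ols_limit"

    def test_balanced_anova_closed_form(self):
        """Balanced one-way: REML equals the classical ANOVA estimators."""
        rng = np.random.default_rng(8)
        G, n_per = 8, 6
        groups = np.repeat(np.arange(G), n_per)
        y = 50 + rng.normal(0, 4.0, G)[groups] + rng.normal(0, 1.5, G * n_per)
        X = np.ones((G * n_per, 1))
        fit = fit_random_intercept_lmm(y, X, groups, slope_index=0)
        gm = y.mean()
        group_means = y.reshape(G, n_per).mean(axis=1)
        msb = n_per * ((group_means - gm) ** 2).sum() / (G - 1)
        msw = ((y.reshape(G, n_per) - group_means[:, None]) ** 2).sum() / (G * (n_per - 1))
        assert fit.beta[0] == pytest.approx(gm, abs=1e-8)
        assert fit.sigma2_e == pytest.approx(msw, rel=1e-6)
        assert fit.sigma2_u == pytest.approx((msb - msw) / n_per, rel=1e-6)
        # between-group contrast df in the balanced case
        assert fit.df == pytest.approx(G - 1, rel=1e-3)

    def test_parameter_recovery_monte_carlo(self):
        """Mean slope estimate over replicates is within 0.1 of truth."""
        rng = np.random.default_rng(17)
        est = [fit_random_intercept_lmm(*simulate_lmm_data(rng, 40, 20)).beta[1]
               for _ in range(200)]
        assert abs(np.mean(est) - (-2.5)) < 0.1

    def test_matches_statsmodels(self):
        from statsmodels.regression.mixed_linear_model import MixedLM
        import warnings
        rng = np.random.default_rng(3)
        for _ in range(5):
            y, X, groups = simulate_lmm_data(rng, int(rng.integers(6, 15)),
                                             int(rng.integers(4, 9)))
            fit = fit_random_intercept_lmm(y, X, groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = MixedLM(y, X, groups).fit(reml=True)
            assert np.allclose(fit.beta, m.fe_params, rtol=1e-4, atol=1e-6)
            assert fit.sigma2_e == pytest.approx(m.scale, rel=1e-3)
            assert fit.sigma2_u == pytest.approx(float(np.atleast_2d(m.cov_re)[0, 0]),
                                                 rel=1e-3, abs=1e-6)
            assert fit.loglik == pytest.approx(m.llf, abs=1e-5)

    def test_loglik_no_worse_than_ols_boundary(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y, X, groups = simulate_lmm_data(rng, 8, 5, s_u=rng.uniform(0, 3))
            fit = fit_random_intercept_lmm(y, X, groups)
            from somnalert.ranking import _GroupData, _neg2_profiled
            gd = _GroupData(y, X, groups)
            val0, _, _ = _neg2_profiled(0.0, gd, True)
            assert -0.5 * val0 <= fit.loglik + 1e-9

    def test_invariant_to_group_labels_and_row_order(self):
        rng = np.random.default_rng(9)
        y, X, groups = simulate_lmm_data(rng, 10, 6)
        fit = fit_random_intercept_lmm(y, X, groups)
        perm = rng.permutation(len(y))
        relabel = np.array([f"g{99 - g}" for g in groups])
        fit2 = fit_random_intercept_lmm(y[perm], X[perm], relabel[perm])
        # theta is located to ~1e-6 relative (flat profiled likelihood)
        assert np.allclose(fit.beta, fit2.beta, atol=1e-8)
        assert fit.sigma2_u == pytest.approx(fit2.sigma2_u, rel=1e-5)
        assert fit.t_score == pytest.approx(fit2.t_score, rel=1e-6)
        assert fit.df == pytest.approx(fit2.df, rel=1e-4)

    def test_df_bounded_by_residual_df(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            y, X, groups = simulate_lmm_data(rng, 6, 4)
            fit = fit_random_intercept_lmm(y, X, groups)
            assert fit.df <= len(y) - X.shape[1] + 1e-9

    def test_singular_design_rejected(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankingError, match="singular"):
            fit_random_intercept_lmm(y, X, np.repeat([0, 1], 5))

    def test_single_group_rejected(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(RankingError, match="2 groups"):
            fit_random_intercept_lmm(y, X, np.zeros(10))


class TestHolm:
    def test_single_p_is_identity(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_evaluated_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_nan_passthrough_reduces_m(self):
        adj = holm_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], [0.02, 0.04])

    def test_invalid_p_rejected(self):
        with pytest.raises(RankingError):
            holm_adjust([0.0, 0.5])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_contract_properties(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone step-down


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -x - 5)[0] == pytest.approx(-1.0)

    def test_midrank_ties_against_bruteforce(self):
        def midranks(v):
            v = np.asarray(v, dtype=float)
            r = np.empty(len(v))
            for i, val in enumerate(v):
                less = np.sum(v < val)
                eq = np.sum(v == val)
                r[i] = less + (eq + 1) / 2.0
            return r

        x = [1, 2, 2, 3, 5, 5, 5, 8]
        y = [3, 1, 4, 4, 6, 9, 6, 10]
        rho, _ = spearman(x, y)
        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestRankParameters:
    @staticmethod
    def matched_cohort(seed):
        from somnalert.features import FEATURE_NAMES
        from somnalert.preprocess import standardize
        from somnalert.synth import SimConfig, simulate_matched_cohort
        cfg = SimConfig(n_participants=40, toss_rate_dispersion=0.0,
                        episode_prob_per_night=0.0, seed=seed)
        df = simulate_matched_cohort(cfg, reports_per_participant=26)
        std, _ = standardize(df, columns=FEATURE_NAMES)
        return std

    def test_driving_parameter_recovered_with_negative_sign(self):
        from somnalert.features import FEATURE_NAMES
        table = rank_parameters(self.matched_cohort(101), FEATURE_NAMES)
        assert table.iloc[0]["parameter"] == "n_toss_turns"
        assert table.iloc[0]["estimate"] < 0
        assert table.iloc[0]["p_adjusted"] < 0.05
        assert (table["rank"] == np.arange(1, len(table) + 1)).all()

    def test_all_missing_parameter_dropped_with_flag(self):
        from somnalert.features import FEATURE_NAMES
        df = self.matched_cohort(102)
        df["n_toss_turns"] = np.nan
        table = rank_parameters(df, FEATURE_NAMES)
        row = table[table["parameter"] == "n_toss_turns"].iloc[0]
        assert not row["converged"] and np.isnan(row["p"])

    def test_holm_column_consistent(self):
        from somnalert.features import FEATURE_NAMES
        table = rank_parameters(self.matched_cohort(103), FEATURE_NAMES)
        ok = table["p"].notna()
        assert np.allclose(table.loc[ok, "p_adjusted"],
                           holm_adjust(table["p"].to_numpy())[ok.to_numpy()])
        assert (table.loc[ok, "p_adjusted"] >= table.loc[ok, "p"] - 1e-15).all()


class TestBiasChecks:
    def test_welch_matches_hand_computation(self):
        matched = pd.DataFrame({"participant_id": ["a", "b", "c"]})
        reports = pd.DataFrame({
            "participant_id": list("abc") + list("xyz"),
            "eqvas": [1, 2, 3, 2, 4, 9],
        })
        miss = pd.DataFrame({"participant_id": list("abcxyz"),
                             "fraction_missing": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]})
        out = bias_checks(matched, reports, miss)
        # Welch t for (1,2,3) vs (2,4,9): t = -3 / sqrt(1/3 + 13/3)
        assert out["welch_t"] == pytest.approx(-3 / np.sqrt(14 / 3), abs=1e-10)
        assert out["n_included"] == 3 and out["n_excluded"] == 3

    def test_identical_groups_give_zero_t(self):
        matched = pd.DataFrame({"participant_id": ["a", "b", "c"]})
        reports = pd.DataFrame({"participant_id": list("abcxyz"),
                                "eqvas": [1, 2, 3, 1, 2, 3]})
        miss = pd.DataFrame({"participant_id": list("abcxyz"),
                             "fraction_missing": np.linspace(0, 1, 6)})
        assert bias_checks(matched, reports, miss)["welch_t"] == pytest.approx(0.0)

    def test_too_few_excluded_skips_t(self):
        matched = pd.DataFrame({"participant_id": ["a", "b", "c"]})
        reports = pd.DataFrame({"participant_id": list("abcx"), "eqvas": [1, 2, 3, 4]})
        miss = pd.DataFrame({"participant_id": list("abcx"),
                             "fraction_missing": [0.1, 0.2, 0.3, 0.4]})
        out = bias_checks(matched, reports, miss)
        assert np.isnan(out["welch_t"]) and "skipped" in out["note"]
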