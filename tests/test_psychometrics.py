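"""EFA, multi-group CFA, invariance ladder, modification indices,
pruning and stress scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressbiome import psychometrics as psy
from stressbiome.psychometrics import (
    GroupedCFA, chisq_diff_test, cronbach_alpha, efa_minres_promax,
    fit_indices, invariance_ladder, model_df, modification_indices,
    aggregate_modification_indices, parallel_analysis, polychoric_matrix,
    prune_to_invariance, score_stress,
)


def _discretize(z):
    return np.digitize(z, [-1.5, -0.5, 0.5, 1.5])


# --------------------------------------------------------------------------
# polychoric correlation
# --------------------------------------------------------------------------

class TestPolychoric:
    def test_unit_diagonal_and_symmetry(self, rng):
        X = pd.DataFrame(rng.integers(0, 5, size=(200, 3)), columns=list("abc"))
        R = polychoric_matrix(X)
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R.to_numpy(), R.to_numpy().T)

    @pytest.mark.parametrize("true_rho", [0.6, 0.0])
    def test_bivariate_normal_recovery(self, rng, true_rho):
        L = np.linalg.cholesky([[1, true_rho], [true_rho, 1]])
        Z = rng.standard_normal((5000, 2)) @ L.T
        R = polychoric_matrix(pd.DataFrame(_discretize(Z), columns=["x", "y"]))
        assert abs(R.loc["x", "y"] - true_rho) < 0.03

    def test_single_category_item_flagged(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 5, 100), "y": np.zeros(100, int)})
        with pytest.warns(UserWarning, match="single-category"):
            R = polychoric_matrix(X)
        assert np.isnan(R.loc["x", "y"])


# --------------------------------------------------------------------------
# parallel analysis / EFA / alpha
# --------------------------------------------------------------------------

class TestEFA:
    def _two_factor_corr(self, rng, loading=0.8, n=1000, phi=0.0):
        k = np.array([[1, phi], [phi, 1]])
        F = rng.standard_normal((n, 2)) @ np.linalg.cholesky(k).T
        lam = np.zeros((8, 2))
        lam[:4, 0] = loading
        lam[4:, 1] = loading
        X = F @ lam.T + rng.standard_normal((n, 8)) * np.sqrt(1 - loading**2)
        return pd.DataFrame(np.corrcoef(X, rowvar=False),
                            index=list("abcdefgh"), columns=list("abcdefgh")), n

    def test_parallel_analysis_counts(self, rng):
        assert parallel_analysis(np.eye(10), n_obs=500, seed=1) == 0
        R2, n = self._two_factor_corr(rng)
        assert parallel_analysis(R2.to_numpy(), n_obs=n, seed=1) == 2
        F = rng.standard_normal(1000)
        X1 = np.outer(F, np.full(6, 0.9)) + rng.standard_normal((1000, 6)) * np.sqrt(1 - 0.81)
        R1 = np.corrcoef(X1, rowvar=False)
        assert parallel_analysis(R1, n_obs=1000, seed=1) == 1

    def test_minres_promax_recovery(self, rng):
        R, _ = self._two_factor_corr(rng)
        res = efa_minres_promax(R, 2)
        L = res.loadings.abs()
        grp0 = L.iloc[:4].idxmax(axis=1)
        grp1 = L.iloc[4:].idxmax(axis=1)
        assert grp0.nunique() == 1 and grp1.nunique() == 1
        assert grp0.iloc[0] != grp1.iloc[0]
        # orthogonal generating factors -> promax correlation near zero
        assert abs(res.factor_corr[0, 1]) < 0.05

    def test_two_factor_beats_one_factor_residuals(self, rng):
        R, _ = self._two_factor_corr(rng, phi=0.3)
        mask = ~np.eye(8, dtype=bool)

        def rmsr(res):
            resid = R.to_numpy() - res.loadings.to_numpy() @ res.factor_corr \
                @ res.loadings.to_numpy().T
            return np.sqrt(np.mean(resid[mask] ** 2))

        assert rmsr(efa_minres_promax(R, 2)) < rmsr(efa_minres_promax(R, 1))

    def test_cronbach_alpha(self, rng):
        x = rng.standard_normal(50)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)
        # exact moments via whitening: 3 items, pairwise cov 0.5, var 1
        Z = rng.standard_normal((200, 3))
        Z = Z - Z.mean(0)
        C = np.cov(Z, rowvar=False, ddof=1)
        W = np.linalg.inv(np.linalg.cholesky(C))
        target = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        X = Z @ W.T @ np.linalg.cholesky(target).T
        assert cronbach_alpha(X) == pytest.approx(0.75)
        X0 = Z @ W.T  # exactly uncorrelated, unit variance
        assert cronbach_alpha(X0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 2)))


# --------------------------------------------------------------------------
# CFA machinery
# --------------------------------------------------------------------------

class TestCFA:
    @pytest.mark.parametrize("n_items,expected", [
        (10, {"configural": 68, "weak": 76, "strong": 84, "strict": 94}),
        (7, {"configural": 26, "weak": 31, "strong": 36, "strict": 43}),
    ])
    def test_model_df_accounting(self, n_items, expected):
        for level, df in expected.items():
            assert model_df(n_items, 2, level) == df

    def test_population_moments_give_zero_discrepancy(self):
        # model-implied moments fed back in -> F = 0 at the truth
        from stressbiome.psychometrics import _CFAModel
        fi = np.array([0, 0, 0, 1, 1, 1])
        model = _CFAModel(fi, 2, "configural")
        lam = np.full(6, 0.8)
        theta = np.full(6, 0.36)
        Phi = np.array([[1.0, -0.4], [-0.4, 1.0]])
        P = Phi[fi][:, fi]
        Sigma = np.outer(lam, lam) * P + np.diag(theta)
        mu = np.arange(6.0)
        stats_g = [(Sigma, mu, 99.0), (Sigma, mu, 79.0)]
        x = model.start(stats_g)
        x[model.sl_lam[0]] = lam
        x[model.sl_lam[1]] = lam
        x[model.sl_nu[0]] = mu
        x[model.sl_nu[1]] = mu
        x[model.sl_theta[0]] = np.log(theta)
        x[model.sl_theta[1]] = np.log(theta)
        x[model.sl_phi[0]] = [-0.4]
        x[model.sl_phi[1]] = [-0.4]
        f, grad = model.objective_grad(x, stats_g)
        assert abs(f) < 1e-10
        assert np.max(np.abs(grad)) < 1e-8

    def test_gradient_matches_finite_differences(self, big_likert):
        from stressbiome.psychometrics import _CFAModel, _group_stats
        X = big_likert[list("abcdefghij")].to_numpy(float)
        labels, sg = _group_stats(X, big_likert["cohort"].to_numpy())
        model = _CFAModel(np.array([0, 0, 0, 1, 1, 0, 1, 1, 0, 0]), 2, "weak")
        x = model.start(sg) + 0.01
        f0, g = model.objective_grad(x, sg)
        num = np.empty_like(x)
        eps = 1e-6
        for i in range(len(x)):
            xp = x.copy(); xp[i] += eps
            xm = x.copy(); xm[i] -= eps
            num[i] = (model.objective_grad(xp, sg)[0]
                      - model.objective_grad(xm, sg)[0]) / (2 * eps)
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-6)

    def test_strict_statistic_is_central_chisq_on_invariant_gaussian_data(self):
        # continuous responses from an invariant model: T ~ chi2(df)
        rng = np.random.default_rng(21)
        df_expected = model_df(10, 2, "strict")
        lam = np.full(10, 0.8)
        fi = np.array([0, 0, 0, 1, 1, 0, 1, 1, 0, 0])
        Phi = np.array([[1, -0.4], [-0.4, 1]])
        Ts = []
        for _ in range(20):
            rows = []
            for _g in range(2):
                F = rng.standard_normal((500, 2)) @ np.linalg.cholesky(Phi).T
                X = F[:, fi] * lam + rng.standard_normal((500, 10))
                rows.append(X)
            X = np.vstack(rows)
            groups = np.repeat(["a", "b"], 500)
            fit = GroupedCFA(level="strict").fit(X, groups)
            Ts.append(fit.statistic_)
        lo = df_expected - 3 * np.sqrt(2 * df_expected)
        hi = df_expected + 3 * np.sqrt(2 * df_expected)
        assert lo < np.mean(Ts) < hi

    def test_configural_statistic_invariances(self, big_likert):
        X = big_likert[list("abcdefghij")]
        g = big_likert["cohort"]
        base = GroupedCFA(level="configural").fit(X, g).statistic_
        swapped = GroupedCFA(level="configural").fit(
            X, g.map({"urban": "suburban", "suburban": "urban"})).statistic_
        reordered = GroupedCFA(level="configural").fit(
            X[list("jihgfedcba")], g).statistic_
        assert base == pytest.approx(swapped, rel=1e-5)
        assert base == pytest.approx(reordered, rel=1e-4)


class TestFitIndices:
    def test_exact_fit(self):
        cfi, tli, rmsea = fit_indices(50.0, 50, 1000.0, 90, 200)
        assert cfi == 1.0 and rmsea == 0.0

    def test_hand_computed_case(self):
        cfi, tli, rmsea = fit_indices(100.0, 50, 1000.0, 90, 200, 1)
        assert cfi == pytest.approx(1 - 50 / 910, abs=1e-9)

    def test_overfit_truncates(self):
        cfi, tli, rmsea = fit_indices(40.0, 50, 1000.0, 90, 200)
        assert rmsea == 0.0 and cfi == 1.0

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(0.0, 0, 10.0, 5, 100)


class TestChisqDiff:
    @pytest.mark.parametrize("dchi,ddf,expected", [
        (4.008, 5, 0.548), (24.187, 8, 0.002), (8.898, 5, 0.113),
        (10.891, 7, 0.143),
    ])
    def test_printed_ladder_pvalues(self, dchi, ddf, expected):
        _, _, p = chisq_diff_test(100.0 + dchi, 50 + ddf, 100.0, 50)
        assert round(p, 3) == expected

    def test_large_statistic_below_millesimal(self):
        _, _, p = chisq_diff_test(100.0 + 41.053, 50 + 10, 100.0, 50)
        assert p < 0.001

    def test_zero_difference(self):
        dchi, ddf, p = chisq_diff_test(100.0, 55, 100.0, 50)
        assert dchi == 0.0 and p == 1.0

    def test_negative_difference_floored(self):
        with pytest.warns(UserWarning, match="floored"):
            dchi, _, p = chisq_diff_test(90.0, 55, 100.0, 50)
        assert dchi == 0.0 and p == 1.0

    def test_non_nested_error(self):
        with pytest.raises(ValueError):
            chisq_diff_test(100.0, 50, 90.0, 50)


# --------------------------------------------------------------------------
# invariance ladder, MI, pruning
# --------------------------------------------------------------------------

class TestInvariance:
    def test_single_cohort_rejected(self, study):
        lik = study.likert[study.likert["cohort"] == "urban"]
        with pytest.raises(ValueError, match="two cohorts"):
            invariance_ladder(lik)

    def test_df_strictly_increase_and_weak_fails_on_planted_gap(self, big_likert):
        ladder = invariance_ladder(big_likert)
        dfs = [ladder.fits[l].df_ for l in ["configural", "weak", "strong", "strict"]]
        assert dfs == sorted(dfs) and len(set(dfs)) == 4
        weak_step = next(s for s in ladder.steps if s["restricted"] == "weak")
        assert weak_step["p"] < 0.05
        assert ladder.verdict == "non-invariant at weak"

    def test_invariant_data_pass(self, invariant_likert):
        ladder = invariance_ladder(invariant_likert)
        assert all(s["p"] > 0.05 for s in ladder.steps)
        assert ladder.verdict == "invariant at strict"

    def test_modification_indices_identify_planted_items(self, big_likert):
        X = big_likert[list("abcdefghij")]
        fit = GroupedCFA(level="weak").fit(X, big_likert["cohort"])
        agg = aggregate_modification_indices(modification_indices(fit))
        top3 = set(agg["statistic"].nlargest(3).index)
        assert top3 == {"e", "f", "h"}
        assert (agg["statistic"].dropna() >= 0).all()

    def test_mi_nonnegative_and_near_zero_for_binding_constraint(self, invariant_likert):
        X = invariant_likert[list("abcdefghij")]
        fit = GroupedCFA(level="weak").fit(X, invariant_likert["cohort"])
        mi = modification_indices(fit)
        assert (mi["statistic"].dropna() >= 0).all()
        # invariant data: no constraint should look strongly violated
        assert mi["statistic"].max() < stats.chi2.isf(1e-4, 1)


class TestPruning:
    def test_already_invariant_keeps_all_items(self, invariant_likert):
        fmap, history = prune_to_invariance(invariant_likert)
        assert sorted(fmap) == list("abcdefghij")
        assert history[-1]["status"] == "invariant"

    def test_planted_items_removed(self, big_likert):
        fmap, history = prune_to_invariance(big_likert)
        assert sorted(set("abcdefghij") - set(fmap)) == ["e", "f", "h"]
        assert sorted(fmap) == list("abcdgij")

    def test_deterministic_given_data(self, big_likert):
        f1, h1 = prune_to_invariance(big_likert)
        f2, h2 = prune_to_invariance(big_likert)
        assert f1 == f2
        assert [h["removed"] for h in h1] == [h["removed"] for h in h2]

    def test_factor_floor_respected(self, big_likert):
        fmap, history = prune_to_invariance(big_likert, min_items_per_factor=2)
        counts = pd.Series(list(fmap.values())).value_counts()
        assert (counts >= 2).all()


class TestScoring:
    def test_reverse_scoring_convention(self):
        lik = pd.DataFrame(0, index=["p1"], columns=list("abcdefghij"))
        lik.insert(0, "cohort", "urban")
        s = score_stress(lik)
        assert s.loc["p1", "ED"] == 0
        # four SE items reverse-scored: PS = 0 + (4*4 - 0)
        assert s.loc["p1", "PS"] == 16

    def test_reduced_scores_and_ratio(self):
        lik = pd.DataFrame(4, index=["p1"], columns=list("abcdefghij"))
        lik.loc["p1", list("abcij")] = 2  # rED = 2*5 = 10? use explicit values
        lik = pd.DataFrame(
            [[4, 4, 0, 4, 0, 0, 4, 0, 0, 0]], index=["p1"],
            columns=list("abcdefghij"))
        s = score_stress(lik, retained_items=list("abcdgij"))
        assert s.loc["p1", "rSE"] == 8      # items d,g at 4 each
        assert s.loc["p1", "rED"] == 8      # a,b at 4
        assert s.loc["p1", "rRatio"] == pytest.approx(1.0)

    def test_zero_rse_gives_missing_ratio_and_nan_propagates(self):
        lik = pd.DataFrame(
            [[1, 1, 1, 0, 0, 1, 0, 0, 1, 1],
             [np.nan, 1, 1, 1, 1, 1, 1, 1, 1, 1]],
            index=["p1", "p2"], columns=list("abcdefghij"))
        s = score_stress(lik, retained_items=list("abcdgij"))
        assert np.isnan(s.loc["p1", "rRatio"])
        assert np.isnan(s.loc["p2", "rED"]) and np.isnan(s.loc["p2", "PS"])
        assert s.loc["p2", "rSE"] == 2
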