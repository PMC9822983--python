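"""Planted-truth recovery and calibration experiments.

Each function generates data under the study's assumed model (via
:mod:`stressbiome.simulate` or direct draws from the relevant generating
model), runs the corresponding estimator, and returns summary metrics.
These experiments back the package's validation battery: because the
study's questionnaire and cytokine tables are not public, the pipeline's
claims are checked by recovery of planted effects and calibration under
the null rather than by re-computing the original cohort tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stressbiome.simulate import StudyConfig, simulate_study
from stressbiome import psychometrics as psy
from stressbiome import microbiome as mb
from stressbiome import diffabund as da
from stressbiome import association as assoc
from stressbiome.networks import SparCC, sparcc, bootstrap_edges


def _child_seeds(seed, n):
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


# --------------------------------------------------------------------------
# analytic table checks
# --------------------------------------------------------------------------

def chisq_ladder_pvalues():
    """p-values of the nested chi-square difference tests from the
    study's printed (Chisq.diff, Df.diff) pairs (full and reduced PSS-10
    invariance ladders)."""
    pairs = {
        "reduced_weak": (4.008, 5),
        "full_weak": (24.187, 8),
        "reduced_strong": (8.898, 5),
        "reduced_strict": (10.891, 7),
        "full_strict": (41.053, 10),
    }
    return {k: psy.chisq_diff_test(dchi, ddf, 0.0, 0)[2]
            for k, (dchi, ddf) in pairs.items()}


def cohort_percentages():
    """Cohort summary percentages recomputed from printed counts and
    cohort sizes (urban n=38, suburban n=46)."""
    return {
        "urban_obese_pct": 17 / 38 * 100,
        "suburban_obese_pct": 13 / 46 * 100,
        "suburban_bachelor_pct": 28 / 46 * 100,
    }


# --------------------------------------------------------------------------
# psychometrics recovery
# --------------------------------------------------------------------------

def pruning_recovery(n_reps=50, n_per_group=2000, seed=0):
    """Fraction of replicates in which iterative invariance pruning
    removes exactly the planted non-invariant item set {e, f, h}.

    Uses single-visit (T2) responses so rows are independent
    participants; run in the large-sample regime where every stage of
    the iterative procedure has power.
    """
    seeds = _child_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        st = simulate_study(StudyConfig(n_urban=n_per_group, n_suburban=n_per_group,
                                        seed=int(s)))
        lik = st.likert[st.metadata["trimester"] == "T2"]
        fmap, _ = psy.prune_to_invariance(lik)
        removed = sorted(set(psy.DEFAULT_ITEM_FACTOR_MAP) - set(fmap))
        hits += removed == ["e", "f", "h"]
    return {"prune_recovery_frac": hits / n_reps, "n": n_reps}


def mi_refit_agreement(n_per_group=1000, seed=0):
    """Relative error between the modification index and the actual
    refit chi-square drop, at the weak-level loading constraint with the
    largest refit drop (the constraint pruning would act on).

    The score statistic approximates the refit drop for small-to-moderate
    releases (its quadratic expansion degrades for very large ones), so
    the check plants a small loading gap.
    """
    st = simulate_study(StudyConfig(n_urban=n_per_group, n_suburban=n_per_group,
                                    noninvariant_loading_gap=0.1,
                                    noninvariant_intercept_gap=0.0,
                                    seed=int(_child_seeds(seed, 1)[0])))
    lik = st.likert[st.metadata["trimester"] == "T2"]
    X = lik[[c for c in lik.columns if c in psy.DEFAULT_ITEM_FACTOR_MAP]]
    g = lik["cohort"]
    fit = psy.GroupedCFA(level="weak").fit(X, g)
    mi = psy.modification_indices(fit).set_index("item")
    best_err, best_dchi = np.nan, -np.inf
    for item in fit.items_:
        refit = psy.GroupedCFA(level="weak").fit(X, g, releases=[("lam", item)])
        dchi = fit.statistic_ - refit.statistic_
        if dchi > best_dchi:
            best_dchi = dchi
            best_err = abs(mi.loc[item, "statistic"] - dchi) / dchi
    return {"mi_refit_max_rel_err": float(best_err), "n": 1,
            "refit_dchi": float(best_dchi)}


# --------------------------------------------------------------------------
# kinship LMM recovery
# --------------------------------------------------------------------------

def _kinship_dataset(rng, n_participants=84, m_genera=100, b2=0.8,
                     s2_participant=0.1, s2_residual=0.1):
    """y = g + u + e with g drawn from a genus-profile kinship at the
    planted b^2 (denominator includes the participant variance)."""
    n = 2 * n_participants
    Z = rng.standard_normal((n, m_genera))
    Z = (Z - Z.mean(0)) / Z.std(0)
    K = Z @ Z.T / m_genera
    total = s2_participant + s2_residual
    s2_k = b2 / (1 - b2) * total if b2 < 1 else 1.0
    w, V = np.linalg.eigh(K)
    g = V @ (np.sqrt(np.clip(w, 0, None) * s2_k) * rng.standard_normal(n))
    parts = np.repeat(np.arange(n_participants), 2)
    u = np.sqrt(s2_participant) * rng.standard_normal(n_participants)[parts]
    e = np.sqrt(s2_residual) * rng.standard_normal(n)
    y = g + u + e
    X = np.ones((n, 1))
    return y, X, K, parts


def kinship_recovery(n_reps=50, b2=0.8, n_participants=84, m_genera=100,
                     gain_threshold=0.25, seed=0):
    """Mean b-hat^2 at planted b^2 and the fraction of replicates with
    ten-fold cross-validated predictive gain above ``gain_threshold``."""
    seeds = _child_seeds(seed, n_reps)
    b2s, gains = [], []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        y, X, K, parts = _kinship_dataset(rng, n_participants, m_genera, b2)
        fit = assoc.KinshipLMM().fit(X, y, K=K, participants=parts)
        b2s.append(fit.b2_)
        _, _, gain = assoc.cv_predictive_gain(y, X, K, participants=parts,
                                              folds=10, seed=int(s))
        gains.append(gain)
    gains = np.asarray(gains)
    return {
        "b2_mean": float(np.mean(b2s)),
        "cv_gain_frac_above": float(np.mean(gains > gain_threshold)),
        "cv_gain_mean": float(gains.mean()),
        "n": n_reps,
    }


def lrt_calibration(n_reps=200, n_participants=40, m_genera=50, alpha=0.05,
                    seed=0):
    """Type-I error of the boundary LRT for the kinship component under
    sigma2_kinship = 0."""
    seeds = _child_seeds(seed, n_reps)
    rej = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        y, X, K, parts = _kinship_dataset(rng, n_participants, m_genera, b2=0.0,
                                          s2_participant=0.3, s2_residual=0.7)
        fw = assoc.KinshipLMM().fit(X, y, K=K, participants=parts)
        fo = assoc.KinshipLMM(include_kinship=False).fit(X, y, participants=parts)
        _, p = assoc.lrt_variance(fw, fo)
        rej += p < alpha
    return {"lrt_type1": rej / n_reps, "n": n_reps}


# --------------------------------------------------------------------------
# ZIG calibration and recovery
# --------------------------------------------------------------------------

def zig_null_calibration(n_reps=20, seed=0):
    """Mean fraction of features with q < 0.05 when no effects are
    planted (full-null generator)."""
    seeds = _child_seeds(seed, n_reps)
    fracs = []
    for s in seeds:
        cfg = StudyConfig(seed=int(s), planted_effects=(), cytokine_coupling=())
        st = simulate_study(cfg)
        qc, _ = mb.qc_filter(st.asv_counts)
        norm = mb.CSSNormalizer().fit(qc)
        scores = psy.score_stress(st.likert, retained_items=list("abcdgij"))
        res = da.associate(qc, scores[["rSE"]],
                           covariates=st.metadata[["site", "age"]],
                           offset=norm.log2_offsets())
        fracs.append(float((res["q"] < 0.05).mean()))
    return {"zig_null_q05_frac": float(np.mean(fracs)), "n": n_reps}


def zig_sign_recovery(n_reps=50, seed=0):
    """Recovery of the planted negative Self-Efficacy effect on the
    B. uniformis-like taxon: fraction of replicates with a negative
    fitted coefficient, and with a negative coefficient at q < 0.05."""
    seeds = _child_seeds(seed, n_reps)
    neg, neg_sig = 0, 0
    for s in seeds:
        st = simulate_study(StudyConfig(seed=int(s)))
        qc, _ = mb.qc_filter(st.asv_counts)
        norm = mb.CSSNormalizer().fit(qc)
        scores = psy.score_stress(st.likert, retained_items=list("abcdgij"))
        res = da.associate(qc, scores[["rSE"]],
                           covariates=st.metadata[["site", "age"]],
                           offset=norm.log2_offsets())
        row = res[res["feature"] == "B_uniformis_like"]
        if len(row):
            neg += bool(row["beta"].iloc[0] < 0)
            neg_sig += bool((row["beta"].iloc[0] < 0) & (row["q"].iloc[0] < 0.05))
    return {"zig_sign_recovery_frac": neg / n_reps,
            "zig_sig_recovery_frac": neg_sig / n_reps, "n": n_reps}


def zig_ols_equivalence(n=120, k=3, seed=0):
    """Max |ZIG - OLS| coefficient difference on zero-free data."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + 0.5 * rng.standard_normal(n) + 10.0
    fit = da.ZeroInflatedGaussianRegressor().fit(X, y, depth=np.full(n, 1e4))
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    return {"zig_ols_max_abs_diff": float(np.max(np.abs(fit.coef_ - ols))), "n": n}


# --------------------------------------------------------------------------
# PERMANOVA calibration
# --------------------------------------------------------------------------

def permanova_calibration(n_reps=200, n=40, n_taxa=30, n_perm=199, alpha=0.05,
                          seed=0):
    """Type-I error of the group term on random compositions with random
    labels (cohort-style covariate included first)."""
    seeds = _child_seeds(seed, n_reps)
    rej = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        counts = rng.poisson(np.exp(rng.normal(2, 1, size=(n, n_taxa))))
        counts = pd.DataFrame(counts + 1)
        design = pd.DataFrame({
            "cohort": rng.choice(["a", "b"], n),
            "group": rng.choice(["x", "y"], n),
        })
        res = mb.permanova(mb.bray_curtis(counts), design, ["cohort", "group"],
                           n_perm=n_perm, seed=int(s))
        rej += res.loc["group", "p"] <= alpha
    return {"permanova_type1": rej / n_reps, "n": n_reps}


# --------------------------------------------------------------------------
# SparCC calibration
# --------------------------------------------------------------------------

def sparcc_null(n_reps=20, n=200, n_taxa=50, seed=0):
    """Mean absolute SparCC correlation on independent log-normal
    compositions."""
    seeds = _child_seeds(seed, n_reps)
    means = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        basis = np.exp(rng.normal(0, 1, size=(n, n_taxa)))
        frac = basis / basis.sum(1, keepdims=True)
        counts = np.vstack([rng.multinomial(20000, f) for f in frac])
        est = SparCC(seed=int(s)).fit(counts)
        iu = np.triu_indices(n_taxa, 1)
        means.append(float(np.abs(est.correlations_[iu]).mean()))
    return {"sparcc_null_mean_abs_r": float(np.mean(means)), "n": n_reps}


def bootstrap_edge_fpr(n_reps=20, n=150, n_taxa=45, n_boot=100, seed=0):
    """False-positive edge fraction of the 3-SD bootstrap rule on
    independent data."""
    seeds = _child_seeds(seed, n_reps)
    fracs = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        basis = np.exp(rng.normal(0, 1, size=(n, n_taxa)))
        frac = basis / basis.sum(1, keepdims=True)
        counts = np.vstack([rng.multinomial(20000, f) for f in frac])
        res = sparcc(counts, seed=int(s))
        edges = bootstrap_edges(counts, res, n_boot=n_boot, seed=int(s))
        fracs.append(float(edges["significant"].mean()))
    return {"bootstrap_edge_fpr": float(np.mean(fracs)), "n": n_reps}


# --------------------------------------------------------------------------
# remaining oracle equivalences
# --------------------------------------------------------------------------

def blup_ridge_equivalence(n_train=30, n_test=10, m=12, seed=0):
    """Kinship-BLUP prediction vs the explicit ridge dual on standardized
    genus features (fixed variance components, no fitting)."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_train + n_test, m))
    Z = (Z - Z[:n_train].mean(0)) / Z[:n_train].std(0)
    Zt = Z / np.sqrt(m)
    K = Zt @ Zt.T
    y = rng.standard_normal(n_train)
    s2k, s2e = 0.7, 0.4
    V = s2k * K[:n_train, :n_train] + s2e * np.eye(n_train)
    blup = s2k * K[n_train:, :n_train] @ np.linalg.solve(V, y)
    lam = s2e / s2k
    ridge_coef = np.linalg.solve(
        Zt[:n_train].T @ Zt[:n_train] + lam * np.eye(m), Zt[:n_train].T @ y)
    ridge = Zt[n_train:] @ ridge_coef
    return {"blup_ridge_max_abs_diff": float(np.max(np.abs(blup - ridge))),
            "n": n_test}


def reml_grid_agreement(n_participants=20, m=30, seed=0):
    """b^2 from the REML optimizer vs a dense log-variance grid search on
    a toy problem."""
    rng = np.random.default_rng(seed)
    y, X, K, parts = _kinship_dataset(rng, n_participants, m, b2=0.5,
                                      s2_participant=0.2, s2_residual=0.3)
    fit = assoc.KinshipLMM().fit(X, y, K=K, participants=parts)
    ll_grid, comps = assoc.reml_grid_search(y, X, K=K, participants=parts,
                                            grid_size=25)
    tot = sum(comps.values())
    b2_grid = comps["s2_kinship"] / tot
    return {
        "reml_grid_b2_abs_diff": float(abs(fit.b2_ - b2_grid)),
        "reml_minus_grid_loglik": float(fit.reml_loglik_ - ll_grid),
        "n": 2 * n_participants,
    }
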