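"""Microbiome association index: genus-level kinship matrix, two
variance-component REML linear mixed model, b^2 estimation, stepwise
covariate selection, boundary LRT, and participant-stratified ten-fold
cross-validated predictive gain.

The association index b^2 is the fraction of a trait's variance
attributable to a microbiome-derived sample-similarity (kinship) matrix
K in the model

    y = X beta + g + u + e,   cov(g) = s2_k K,
                              cov(u) = s2_p (participant blocks),
                              cov(e) = s2_e I,

    b^2 = s2_k / (s2_k + s2_p + s2_e).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin


# --------------------------------------------------------------------------
# kinship construction
# --------------------------------------------------------------------------

def genus_aggregate(normalized: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Sum normalized abundances over ASVs sharing a genus label.

    ASVs with an empty genus are pooled per family under an explicit
    ``unclassified_<family>`` label. Returns samples x genera.
    """
    if "genus" not in taxonomy.columns:
        raise ValueError("taxonomy lacks genus annotations")
    genus = taxonomy["genus"].reindex(normalized.columns)
    if genus.isna().all() or (genus.fillna("") == "").all():
        raise ValueError("no genus annotations available")
    family = taxonomy.get("family", pd.Series("", index=taxonomy.index))
    family = family.reindex(normalized.columns).fillna("")
    labels = genus.fillna("").where(
        genus.fillna("") != "", "unclassified_" + family
    )
    return normalized.T.groupby(labels).sum().T


def build_kinship(genus_matrix: pd.DataFrame, pseudocount=None):
    """Kinship K = Z Z' / m from log-transformed, per-genus standardized
    genus abundances (m genera).

    The pseudocount defaults to half the smallest nonzero value. Constant
    genera are dropped with a warning; negative eigenvalues (numerical)
    are clipped at zero.
    """
    M = np.asarray(genus_matrix, float)
    if M.shape[1] < 2:
        raise ValueError("kinship needs at least two genera")
    if pseudocount is None:
        nz = M[M > 0]
        pseudocount = (nz.min() / 2.0) if nz.size else 1e-6
    L = np.log(M + pseudocount)
    sd = L.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genera")
    L = L[:, keep]
    Z = (L - L.mean(axis=0)) / L.std(axis=0, ddof=0)
    K = Z @ Z.T / Z.shape[1]
    w, V = np.linalg.eigh(K)
    if w.min() < -1e-8:
        warnings.warn("clipping negative kinship eigenvalues at 0")
        K = (V * np.clip(w, 0, None)) @ V.T
    idx = genus_matrix.index if isinstance(genus_matrix, pd.DataFrame) else None
    return pd.DataFrame(K, index=idx, columns=idx)


# --------------------------------------------------------------------------
# REML variance components
# --------------------------------------------------------------------------

def _participant_blocks(groups) -> np.ndarray:
    g = pd.factorize(np.asarray(groups))[0]
    return (g[:, None] == g[None, :]).astype(float)


def _reml_loglik(log_s2, y, X, comps):
    s2 = np.exp(log_s2)
    n, p = X.shape
    V = sum(s * C for s, C in zip(s2, comps))
    try:
        cho = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -1e12
    logdetV = 2 * np.sum(np.log(np.diag(cho)))
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -1e12
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    quad = float(y @ Py)
    return -0.5 * (logdetV + logdetXVX + quad + (n - p) * np.log(2 * np.pi))


class KinshipLMM(BaseEstimator, RegressorMixin):
    """REML linear mixed model with a kinship kernel and an optional
    participant random intercept.

    Parameters
    ----------
    include_kinship : bool
        If False, the kinship component is omitted (the comparison model).
    b2_denominator : str
        "total" (default) includes the participant variance in the b^2
        denominator; "no_participant" excludes it.

    Attributes
    ----------
    variance_components_ : dict with s2_kinship, s2_participant, s2_residual.
    b2_ : association index.
    fixed_effects_ : GLS estimates at the REML solution.
    reml_loglik_ : maximized restricted log-likelihood.
    converged_ : bool (a dense grid-search fallback runs otherwise).
    """

    def __init__(self, include_kinship=True, b2_denominator="total", maxiter=200):
        self.include_kinship = include_kinship
        self.b2_denominator = b2_denominator
        self.maxiter = maxiter

    def fit(self, X, y, K=None, participants=None):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(y)
        comps, names = [], []
        if self.include_kinship:
            if K is None:
                raise ValueError("include_kinship=True requires K")
            Kv = np.asarray(K, float)
            comps.append(Kv)
            names.append("s2_kinship")
            offdiag = Kv - np.diag(np.diag(Kv))
            if participants is None and np.max(np.abs(offdiag)) < 1e-10:
                warnings.warn("K is (near) identity and no participant term: "
                              "kinship and residual variances unidentifiable")
                self.identifiable_ = False
            else:
                self.identifiable_ = True
        else:
            self.identifiable_ = True
        if participants is not None:
            comps.append(_participant_blocks(participants))
            names.append("s2_participant")
        comps.append(np.eye(n))
        names.append("s2_residual")

        vy = np.var(y, ddof=1)
        x0 = np.full(len(comps), np.log(max(vy, 1e-8) / len(comps)))
        obj = lambda t: -_reml_loglik(t, y, X, comps)
        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                bounds=[(np.log(vy) - 18, np.log(vy) + 6)] * len(comps),
                                options={"maxiter": self.maxiter})
        self.converged_ = bool(res.success)
        best_t, best_f = res.x, res.fun
        if not self.converged_:
            # coarse grid fallback around the variance scale of y
            grid = np.log(vy) + np.linspace(-12, 2, 8)
            from itertools import product
            for t in product(grid, repeat=len(comps)):
                f = obj(np.array(t))
                if f < best_f:
                    best_t, best_f = np.array(t), f
            warnings.warn("REML optimizer did not converge; grid fallback used")

        s2 = dict(zip(names, np.exp(best_t)))
        self.variance_components_ = {
            "s2_kinship": s2.get("s2_kinship", 0.0),
            "s2_participant": s2.get("s2_participant", 0.0),
            "s2_residual": s2["s2_residual"],
        }
        denom = self.variance_components_["s2_kinship"] + self.variance_components_["s2_residual"]
        if self.b2_denominator == "total":
            denom += self.variance_components_["s2_participant"]
        self.b2_ = self.variance_components_["s2_kinship"] / denom if denom > 0 else 0.0
        self.reml_loglik_ = -best_f

        V = sum(np.exp(t) * C for t, C in zip(best_t, comps))
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        self.fixed_effects_ = np.linalg.solve(XtViX, Vi_X.T @ y)
        self._V = V
        self._X = X
        self._y = y
        self._K = None if not self.include_kinship else np.asarray(K, float)
        self._resid_gls = y - X @ self.fixed_effects_
        return self

    def blup(self):
        """In-sample kinship BLUP g_hat = s2_k K V^-1 (y - X beta)."""
        if self._K is None:
            return np.zeros_like(self._y)
        s2k = self.variance_components_["s2_kinship"]
        return s2k * self._K @ np.linalg.solve(self._V, self._resid_gls)

    def predict_new(self, X_new, K_cross=None):
        """Out-of-sample prediction: fixed effects plus the kinship BLUP
        through the train-test kinship block (participant effects are
        zero for unseen participants)."""
        mu = np.asarray(X_new, float) @ self.fixed_effects_
        if self._K is not None and K_cross is not None:
            s2k = self.variance_components_["s2_kinship"]
            mu = mu + s2k * np.asarray(K_cross, float) @ np.linalg.solve(
                self._V, self._resid_gls)
        return mu


def reml_fit(y, X, K=None, participants=None, include_kinship=True, **kw):
    """Functional wrapper around :class:`KinshipLMM`."""
    return KinshipLMM(include_kinship=include_kinship, **kw).fit(
        X, y, K=K, participants=participants)


def reml_grid_search(y, X, K=None, participants=None, grid_size=25, span=12.0):
    """Dense log-variance grid search; independent check of the REML
    optimizer on small problems. Returns (best log-lik, components dict)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    comps, names = [], []
    if K is not None:
        comps.append(np.asarray(K, float)); names.append("s2_kinship")
    if participants is not None:
        comps.append(_participant_blocks(participants)); names.append("s2_participant")
    comps.append(np.eye(len(y))); names.append("s2_residual")
    vy = np.var(y, ddof=1)
    grid = np.log(vy) + np.linspace(-span, 2, grid_size)
    from itertools import product
    best = (-np.inf, None)
    for t in product(grid, repeat=len(comps)):
        ll = _reml_loglik(np.array(t), y, X, comps)
        if ll > best[0]:
            best = (ll, dict(zip(names, np.exp(t))))
    return best


def lrt_variance(fit_with: KinshipLMM, fit_without: KinshipLMM):
    """Boundary likelihood-ratio test for the kinship variance component.

    p = 0.5 P(chi2_0 > LR) + 0.5 P(chi2_1 > LR); a negative statistic is
    floored at 0 with a warning.
    """
    lr = 2.0 * (fit_with.reml_loglik_ - fit_without.reml_loglik_)
    if lr < 0:
        warnings.warn("negative LRT statistic floored at 0")
        lr = 0.0
    p = 1.0 if lr == 0 else 0.5 * float(stats.chi2.sf(lr, 1))
    return lr, p


# --------------------------------------------------------------------------
# covariate selection and cross-validation
# --------------------------------------------------------------------------

def _encode_block(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.get_dummies(col, drop_first=True).to_numpy(float)
    return col.to_numpy(float)[:, None]


def stepwise_covariates(y, candidates: pd.DataFrame, alpha=0.05):
    """Forward selection on a fixed-effects-only OLS model.

    At each round the candidate block with the smallest F-test p-value
    enters if p < ``alpha``; stops when none does. Returns (selected
    names, audit trail of per-round p-values).
    """
    y = np.asarray(y, float)
    selected, audit = [], []
    current = np.ones((len(y), 1))
    while True:
        round_p = {}
        for name in candidates.columns:
            if name in selected:
                continue
            block = _encode_block(candidates[name])
            Xc = np.hstack([current, block])
            full = sm.OLS(y, Xc).fit()
            restr = sm.OLS(y, current).fit()
            fstat = ((restr.ssr - full.ssr) / block.shape[1]) / full.mse_resid
            p = float(stats.f.sf(fstat, block.shape[1], full.df_resid))
            round_p[name] = p
        if not round_p:
            break
        best = min(round_p, key=round_p.get)
        audit.append(dict(round=len(selected) + 1, pvalues=round_p, entered=None))
        if round_p[best] < alpha:
            selected.append(best)
            audit[-1]["entered"] = best
            current = np.hstack([current, _encode_block(candidates[best])])
        else:
            break
    return selected, audit


def cv_predictive_gain(y, X, K, participants=None, folds=10, seed=0):
    """Ten-fold cross-validated R^2 with and without the kinship kernel.

    Folds are stratified by participant (both visits of a participant in
    the same fold). R^2 = 1 - SSE/SST pooled over folds; gain =
    R2_with - R2_without.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    K = np.asarray(K, float)
    n = len(y)
    parts = np.asarray(participants) if participants is not None else np.arange(n)
    uniq = pd.unique(parts)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    assign = {uniq[i]: order[i] % folds for i in range(len(uniq))}
    fold_of = np.array([assign[p] for p in parts])

    preds_with = np.empty(n)
    preds_without = np.empty(n)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if test.sum() < 3:
            raise ValueError(f"fold {f} has fewer than 3 samples")
        part_train = parts[train] if participants is not None else None
        mw = KinshipLMM(include_kinship=True).fit(
            X[train], y[train], K=K[np.ix_(train, train)], participants=part_train)
        preds_with[test] = mw.predict_new(X[test], K[np.ix_(test, train)])
        mo = KinshipLMM(include_kinship=False).fit(
            X[train], y[train], participants=part_train)
        preds_without[test] = mo.predict_new(X[test])

    sst = float(np.sum((y - y.mean()) ** 2))
    r2_with = 1.0 - float(np.sum((y - preds_with) ** 2)) / sst
    r2_without = 1.0 - float(np.sum((y - preds_without) ** 2)) / sst
    return r2_with, r2_without, r2_with - r2_without
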