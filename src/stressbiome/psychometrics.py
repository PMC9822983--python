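"""Two-factor psychometrics of the PSS-10: EFA, multi-group CFA,
measurement-invariance ladder, modification indices, and iterative item
pruning to an invariant reduced scale.

The confirmatory model treats the ten 0-4 Likert items as continuous and
fits a two-factor (Emotional Distress, Self-Efficacy) mean-and-covariance
structure by multi-group maximum likelihood. Invariance levels stack
cross-group equality constraints:

==========  =================================================
configural  same loading pattern, no equality constraints
weak        loadings equal across groups (factor variances
            freed in non-reference groups)
strong      + intercepts equal (factor means freed)
strict      + residual variances equal
==========  =================================================

Identification: factor variances are fixed to 1 and factor means to 0 in
the reference group; each item loads on exactly one factor. Under this
scheme the model degrees of freedom for 10 items / 2 groups are 68
(configural), 76 (weak), 84 (strong) and 94 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from stressbiome.simulate import ITEMS, ED_ITEMS

LEVELS = ["configural", "weak", "strong", "strict"]

DEFAULT_ITEM_FACTOR_MAP = {i: ("ED" if i in ED_ITEMS else "SE") for i in ITEMS}


# --------------------------------------------------------------------------
# model internals
# --------------------------------------------------------------------------

class _CFAModel:
    """Free-parameter bookkeeping for the multi-group one-loading-per-item
    two-factor model at a given invariance level, optionally with released
    cross-group equality constraints (two-group case only)."""

    def __init__(self, fi, n_groups, level, releases=()):
        self.fi = np.asarray(fi)          # factor index (0/1) per item
        self.p = len(fi)
        self.G = n_groups
        self.level = level
        self.releases = list(releases)    # [(kind, item_idx)], kind in lam/nu/theta
        if self.releases and n_groups != 2:
            raise ValueError("constraint release supported for two groups only")
        li = LEVELS.index(level)
        self.share_lam = li >= 1
        self.share_nu = li >= 2
        self.share_theta = li >= 3
        self.free_phi_var = li >= 1       # non-reference factor variances free
        self.free_alpha = li >= 2         # non-reference factor means free
        self._build_layout()

    def _build_layout(self):
        p, G = self.p, self.G
        idx = 0

        def block(size):
            nonlocal idx
            sl = slice(idx, idx + size)
            idx += size
            return sl

        self.sl_lam = block(p) if self.share_lam else [block(p) for _ in range(G)]
        self.sl_nu = block(p) if self.share_nu else [block(p) for _ in range(G)]
        self.sl_theta = block(p) if self.share_theta else [block(p) for _ in range(G)]
        # factor covariance: ref group -> c only; others -> (lv1, lv2, c) when freed
        self.sl_phi = [block(1)] + [
            block(3 if self.free_phi_var else 1) for _ in range(G - 1)
        ]
        self.sl_alpha = [block(2) for _ in range(G - 1)] if self.free_alpha else []
        self.sl_release = block(len(self.releases)) if self.releases else slice(idx, idx)
        self.n_free = idx

    def unpack(self, x):
        """Per-group (lam, nu, theta, Phi, alpha)."""
        p, G = self.p, self.G
        out = []
        deltas = x[self.sl_release]
        for g in range(G):
            lam = np.array(x[self.sl_lam] if self.share_lam else x[self.sl_lam[g]])
            nu = np.array(x[self.sl_nu] if self.share_nu else x[self.sl_nu[g]])
            ltheta = np.array(x[self.sl_theta] if self.share_theta else x[self.sl_theta[g]])
            if g == 1:
                for d, (kind, j) in zip(deltas, self.releases):
                    if kind == "lam":
                        lam = lam.copy(); lam[j] += d
                    elif kind == "nu":
                        nu = nu.copy(); nu[j] += d
                    elif kind == "theta":
                        ltheta = ltheta.copy(); ltheta[j] += d
            theta = np.exp(ltheta)
            ph = x[self.sl_phi[g]]
            if g == 0 or not self.free_phi_var:
                v1 = v2 = 1.0
                c = ph[-1]
            else:
                v1, v2, c = np.exp(ph[0]), np.exp(ph[1]), ph[2]
            Phi = np.array([[v1, c], [c, v2]])
            alpha = np.zeros(2)
            if self.free_alpha and g > 0:
                alpha = np.array(x[self.sl_alpha[g - 1]])
            out.append((lam, nu, theta, Phi, alpha))
        return out

    def start(self, stats_g):
        """Data-driven starting values."""
        x = np.zeros(self.n_free)
        sds = np.mean([np.sqrt(np.diag(S)) for S, _, _ in stats_g], axis=0)
        means = np.mean([m for _, m, _ in stats_g], axis=0)
        lam0 = 0.7 * sds
        ltheta0 = np.log(np.maximum(0.5 * sds**2, 1e-3))
        if self.share_lam:
            x[self.sl_lam] = lam0
        else:
            for sl in self.sl_lam:
                x[sl] = lam0
        if self.share_nu:
            x[self.sl_nu] = means
        else:
            for sl in self.sl_nu:
                x[sl] = means
        if self.share_theta:
            x[self.sl_theta] = ltheta0
        else:
            for sl in self.sl_theta:
                x[sl] = ltheta0
        for g, sl in enumerate(self.sl_phi):
            ph = np.zeros(sl.stop - sl.start)
            ph[-1] = -0.2
            x[sl] = ph
        return x

    def objective_grad(self, x, stats_g):
        """f = sum_g w_g * F_g on the chi-square (T) scale, with gradient.

        w_g = N_g - 1 (Wishart convention); F_g is the ML discrepancy for
        covariance + mean structure.
        """
        params = self.unpack(x)
        p, G = self.p, self.G
        fi = self.fi
        f_total = 0.0
        grad = np.zeros_like(x)
        deltas_grad = np.zeros(len(self.releases))
        for g in range(G):
            S, m, w = stats_g[g]
            lam, nu, theta, Phi, alpha = params[g]
            P = Phi[fi][:, fi]
            Sigma = np.outer(lam, lam) * P + np.diag(theta)
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(x)
            Sinv = np.linalg.inv(Sigma)
            logdet = 2 * np.sum(np.log(np.diag(L)))
            sign_s, logdet_S = np.linalg.slogdet(S)
            mu = nu + lam * alpha[fi]
            d = m - mu
            u = Sinv @ d
            F = logdet + np.trace(S @ Sinv) - logdet_S - p + d @ u
            f_total += w * F

            E = Sinv - Sinv @ S @ Sinv - np.outer(u, u)
            g_lam = 2.0 * ((E * P) @ lam) - 2.0 * u * alpha[fi]
            g_nu = -2.0 * u
            g_theta = np.diag(E) * theta          # wrt log theta
            Lam = np.zeros((p, 2))
            Lam[np.arange(p), fi] = lam
            M = Lam.T @ E @ Lam
            g_alpha = np.array([
                -2.0 * np.sum(u * lam * (fi == 0)),
                -2.0 * np.sum(u * lam * (fi == 1)),
            ])

            if self.share_lam:
                grad[self.sl_lam] += w * g_lam
            else:
                grad[self.sl_lam[g]] += w * g_lam
            if self.share_nu:
                grad[self.sl_nu] += w * g_nu
            else:
                grad[self.sl_nu[g]] += w * g_nu
            if self.share_theta:
                grad[self.sl_theta] += w * g_theta
            else:
                grad[self.sl_theta[g]] += w * g_theta
            if g == 1:
                for r, (kind, j) in enumerate(self.releases):
                    if kind == "lam":
                        deltas_grad[r] += w * g_lam[j]
                    elif kind == "nu":
                        deltas_grad[r] += w * g_nu[j]
                    elif kind == "theta":
                        deltas_grad[r] += w * g_theta[j]

            sl = self.sl_phi[g]
            if g == 0 or not self.free_phi_var:
                grad[sl] += w * np.array([2.0 * M[0, 1]])
            else:
                grad[sl] += w * np.array(
                    [M[0, 0] * Phi[0, 0], M[1, 1] * Phi[1, 1], 2.0 * M[0, 1]]
                )
            if self.free_alpha and g > 0:
                grad[self.sl_alpha[g - 1]] += w * g_alpha
        if self.releases:
            grad[self.sl_release] = deltas_grad
        return f_total, grad

    def df(self, n_moments):
        return n_moments - self.n_free


def _group_stats(X, groups, multiplier="nm1"):
    """Per-group (S, mean, weight) with S on the N_g-1 denominator."""
    labels = list(pd.unique(pd.Series(groups)))
    labels.sort()
    out = []
    for lab in labels:
        Xg = np.asarray(X[np.asarray(groups) == lab], dtype=float)
        Ng = len(Xg)
        S = np.cov(Xg, rowvar=False, ddof=1)
        m = Xg.mean(axis=0)
        w = (Ng - 1) if multiplier == "nm1" else Ng
        out.append((S, m, float(w)))
    return labels, out


def model_df(n_items, n_groups, level):
    """Model degrees of freedom under the package identification scheme."""
    fi = np.zeros(n_items, dtype=int)
    model = _CFAModel(fi, n_groups, level)
    n_moments = n_groups * (n_items * (n_items + 1) // 2 + n_items)
    return model.df(n_moments)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class GroupedCFA(BaseEstimator):
    """Multi-group two-factor confirmatory factor analysis.

    Parameters
    ----------
    item_factor_map : dict, optional
        Item label -> factor name ("ED"/"SE"). Defaults to the canonical
        PSS-10 assignment (ED: a,b,c,f,i,j; SE: d,e,g,h).
    level : str
        Invariance level: "configural", "weak", "strong" or "strict".
    multiplier : str
        "nm1" (default) weights each group's discrepancy by N_g - 1;
        "n" uses N_g.

    Attributes (after :meth:`fit`)
    ------------------------------
    statistic_ : float
        Likelihood-ratio chi-square T against the saturated model.
    df_, cfi_, tli_, rmsea_ : model fit summary.
    loadings_, intercepts_, residual_vars_, factor_cov_, factor_means_ :
        dict keyed by group label.
    converged_ : bool
    """

    def __init__(self, item_factor_map=None, level="configural", multiplier="nm1",
                 maxiter=500):
        self.item_factor_map = item_factor_map
        self.level = level
        self.multiplier = multiplier
        self.maxiter = maxiter

    def fit(self, X, groups, releases=()):
        if self.level not in LEVELS:
            raise ValueError(f"unknown invariance level {self.level!r}")
        fmap = self.item_factor_map or DEFAULT_ITEM_FACTOR_MAP
        if isinstance(X, pd.DataFrame):
            items = [c for c in X.columns if c in fmap]
            data = X[items].to_numpy(float)
        else:
            items = sorted(fmap)
            data = np.asarray(X, float)
        if data.shape[1] != len(items):
            raise ValueError("column/item mismatch")
        factors = sorted(set(fmap[i] for i in items))
        fi = np.array([factors.index(fmap[i]) for i in items])
        labels, stats_g = _group_stats(data, groups, self.multiplier)
        n_per_group = pd.Series(groups).value_counts()

        release_idx = [(kind, items.index(it)) for kind, it in releases]
        model = _CFAModel(fi, len(labels), self.level, release_idx)
        if any(n_per_group[lab] <= model.n_free / len(labels) for lab in labels):
            warnings.warn("group size close to or below free-parameter count")

        x0 = model.start(stats_g)
        res = optimize.minimize(
            model.objective_grad, x0, args=(stats_g,), jac=True,
            method="L-BFGS-B", options={"maxiter": self.maxiter, "ftol": 1e-12,
                                        "gtol": 1e-8},
        )
        # L-BFGS-B line searches occasionally stall; cold restarts from the
        # current iterate usually finish the job
        for _ in range(3):
            if res.success or np.max(np.abs(res.jac)) < 1e-3:
                break
            res = optimize.minimize(
                model.objective_grad, res.x, args=(stats_g,), jac=True,
                method="L-BFGS-B", options={"maxiter": self.maxiter,
                                            "ftol": 1e-13, "gtol": 1e-8},
            )
        self.items_ = items
        self.factors_ = factors
        self.group_labels_ = labels
        self._model = model
        self._stats_g = stats_g
        self._x = res.x
        self.converged_ = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        self.n_iter_ = res.nit
        self.discrepancy_ = float(res.fun)
        self.statistic_ = max(float(res.fun), 0.0)
        n_moments = len(labels) * (len(items) * (len(items) + 1) // 2 + len(items))
        self.df_ = model.df(n_moments)

        params = model.unpack(res.x)
        self.loadings_, self.intercepts_ = {}, {}
        self.residual_vars_, self.factor_cov_, self.factor_means_ = {}, {}, {}
        for lab, (lam, nu, theta, Phi, alpha) in zip(labels, params):
            self.loadings_[lab] = pd.Series(lam, index=items)
            self.intercepts_[lab] = pd.Series(nu, index=items)
            th = np.maximum(theta, 1e-6)
            if np.any(theta < 1e-6):
                warnings.warn("negative/zero residual variance bounded at 1e-6")
            self.residual_vars_[lab] = pd.Series(th, index=items)
            self.factor_cov_[lab] = pd.DataFrame(Phi, index=factors, columns=factors)
            self.factor_means_[lab] = pd.Series(alpha, index=factors)

        Tb, dfb = self._baseline()
        self.baseline_statistic_, self.baseline_df_ = Tb, dfb
        N = int(sum(n_per_group))
        self.cfi_, self.tli_, self.rmsea_ = fit_indices(
            self.statistic_, self.df_, Tb, dfb, N, len(labels)
        )
        return self

    def _baseline(self):
        """Independence (diagonal covariance, free means) model, closed form."""
        T = 0.0
        p = len(self.items_)
        for S, m, w in self._stats_g:
            T += w * (np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
        dfb = len(self.group_labels_) * (p * (p + 1) // 2 + p) - \
            len(self.group_labels_) * 2 * p
        return float(T), dfb


# --------------------------------------------------------------------------
# fit indices and nested tests
# --------------------------------------------------------------------------

def fit_indices(T, df, T_baseline, df_baseline, N, n_groups=1):
    """(CFI, TLI, RMSEA) from model and independence-baseline chi-squares."""
    if df == 0:
        raise ValueError("RMSEA undefined for a saturated model (df = 0)")
    num = max(T - df, 0.0)
    den = max(T_baseline - df_baseline, T - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rb = T_baseline / df_baseline
    tli = ((rb - T / df) / (rb - 1.0)) if rb != 1.0 else 1.0
    rmsea = np.sqrt(n_groups * max(T - df, 0.0) / (df * (N - 1)))
    return float(cfi), float(tli), float(rmsea)


def chisq_diff_test(T_restricted, df_restricted, T_free, df_free):
    """Nested-model chi-square difference test.

    Returns (delta_chisq, delta_df, p). A negative plain difference (which
    the unscaled statistic can produce in finite samples) is floored at
    zero with a warning, giving p = 1.
    """
    ddf = df_restricted - df_free
    if ddf <= 0:
        raise ValueError("models are not nested (df_restricted must exceed df_free)")
    dchi = T_restricted - T_free
    if dchi < 0:
        warnings.warn("negative chi-square difference floored at 0")
        dchi = 0.0
    p = float(stats.chi2.sf(dchi, ddf)) if dchi > 0 else 1.0
    return float(dchi), int(ddf), p


@dataclass
class InvarianceLadderResult:
    fits: dict
    steps: list
    verdict: str
    halted_at: str | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for lev in LEVELS:
            if lev not in self.fits:
                break
            fit = self.fits[lev]
            row = dict(level=lev, df=fit.df_, chisq=round(fit.statistic_, 3))
            for st in self.steps:
                if st["restricted"] == lev:
                    row.update(chisq_diff=round(st["dchi2"], 3),
                               df_diff=st["ddf"], p=round(st["p"], 4))
            rows.append(row)
        return pd.DataFrame(rows)


def invariance_ladder(likert, item_factor_map=None, group_col="cohort",
                      alpha=0.05, multiplier="nm1"):
    """Fit configural -> weak -> strong -> strict with pairwise nested tests.

    `likert` is a DataFrame whose group column holds the cohort label and
    whose remaining (mapped) columns are item responses.
    """
    fmap = item_factor_map or DEFAULT_ITEM_FACTOR_MAP
    groups = likert[group_col]
    if groups.nunique() < 2:
        raise ValueError("invariance analysis requires at least two cohorts")
    X = likert[[c for c in likert.columns if c in fmap]]
    fits, steps = {}, []
    prev = None
    halted = None
    for lev in LEVELS:
        fit = GroupedCFA(fmap, level=lev, multiplier=multiplier).fit(X, groups)
        fits[lev] = fit
        if not fit.converged_:
            halted = lev
            break
        if prev is not None:
            dchi, ddf, p = chisq_diff_test(fit.statistic_, fit.df_,
                                           prev.statistic_, prev.df_)
            steps.append(dict(free=prev.level, restricted=lev,
                              dchi2=dchi, ddf=ddf, p=p))
        prev = fit
    passed = [st for st in steps if st["p"] > alpha]
    if halted:
        verdict = f"non-convergence at {halted}"
    elif len(passed) == len(steps) and len(steps) == 3:
        verdict = "invariant at strict"
    else:
        first_fail = next(st for st in steps if st["p"] <= alpha)
        verdict = f"non-invariant at {first_fail['restricted']}"
    return InvarianceLadderResult(fits, steps, verdict, halted)


# --------------------------------------------------------------------------
# modification indices and pruning
# --------------------------------------------------------------------------

_LEVEL_CONSTRAINTS = {
    "weak": ("lam",),
    "strong": ("lam", "nu"),
    "strict": ("lam", "nu", "theta"),
}


def modification_indices(fit: GroupedCFA) -> pd.DataFrame:
    """Univariate score (Lagrange-multiplier) statistics for every active
    cross-group equality constraint of a constrained fit.

    Each statistic is the expected chi-square drop from releasing that one
    constraint, computed from the gradient and Hessian of the discrepancy
    at the constrained optimum: MI = g_j^2 / (2 s_j) with s_j the Schur
    complement of the released direction. Also returns per-item aggregates
    (sum of the item's constraint statistics).
    """
    if fit.level not in _LEVEL_CONSTRAINTS:
        raise ValueError("modification indices require a constrained level")
    if len(fit.group_labels_) != 2:
        raise ValueError("two-group fits only")
    kinds = _LEVEL_CONSTRAINTS[fit.level]
    releases = [(k, j) for k in kinds for j in range(len(fit.items_))]
    model = _CFAModel(fit._model.fi, 2, fit.level, releases)
    n0 = fit._model.n_free
    x = np.concatenate([fit._x, np.zeros(len(releases))])

    f0, g0 = model.objective_grad(x, fit._stats_g)
    n = model.n_free
    H = np.empty((n, n))
    eps = 1e-5
    for i in range(n):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        _, gp = model.objective_grad(xp, fit._stats_g)
        _, gm = model.objective_grad(xm, fit._stats_g)
        H[i] = (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)

    A = slice(0, n0)
    rows = []
    try:
        cho = np.linalg.cholesky(H[A, A] + 1e-9 * np.eye(n0))
    except np.linalg.LinAlgError:
        cho = None
    for r, (kind, j) in enumerate(releases):
        jj = n0 + r
        gj = g0[jj]
        hj = H[A, jj]
        if cho is not None:
            z = np.linalg.solve(cho, hj)
            s = H[jj, jj] - z @ z
        else:
            s = np.nan
        mi = (gj**2) / (2 * s) if (np.isfinite(s) and s > 1e-10) else np.nan
        rows.append(dict(kind=kind, item=fit.items_[j], statistic=mi,
                         p=float(stats.chi2.sf(mi, 1)) if np.isfinite(mi) else np.nan))
    out = pd.DataFrame(rows)
    return out


def aggregate_modification_indices(mi: pd.DataFrame) -> pd.DataFrame:
    """Per-item aggregate: sum of the item's constraint statistics with
    df = number of summed (finite) constraints."""
    rows = []
    for item, sub in mi.groupby("item", sort=False):
        vals = sub["statistic"].dropna()
        if len(vals) == 0:
            rows.append(dict(item=item, statistic=np.nan, df=0, p=np.nan))
            continue
        stat = float(vals.sum())
        dfi = int(len(vals))
        rows.append(dict(item=item, statistic=stat, df=dfi,
                         p=float(stats.chi2.sf(stat, dfi))))
    return pd.DataFrame(rows).set_index("item")


def prune_to_invariance(likert, item_factor_map=None, group_col="cohort",
                        alpha=0.05, min_items_per_factor=2, multiplier="nm1"):
    """Iteratively remove the most non-invariant item until the weak,
    strong and strict nested comparisons all exceed ``alpha``.

    At each failing step, modification indices are computed at the first
    failing level and the item with the largest per-item aggregate
    statistic (lowest p; ties broken by item label order) is dropped,
    subject to every factor retaining ``min_items_per_factor`` items.

    Returns (retained_map, history); history records each round's ladder
    table and the removed item. ``history[-1]['status']`` is "invariant"
    or "floor_reached".
    """
    fmap = dict(item_factor_map or DEFAULT_ITEM_FACTOR_MAP)
    history = []
    while True:
        ladder = invariance_ladder(likert, fmap, group_col, alpha, multiplier)
        failing = [st for st in ladder.steps if st["p"] <= alpha]
        entry = dict(items=sorted(fmap), ladder=ladder.table(), removed=None,
                     status=None)
        if ladder.halted_at is not None:
            entry["status"] = f"non-convergence at {ladder.halted_at}"
            history.append(entry)
            return fmap, history
        if not failing:
            entry["status"] = "invariant"
            history.append(entry)
            return fmap, history
        level = failing[0]["restricted"]
        mi = modification_indices(ladder.fits[level])
        agg = aggregate_modification_indices(mi)
        counts = pd.Series(list(fmap.values())).value_counts()
        candidates = [
            it for it in sorted(fmap)
            if counts[fmap[it]] > min_items_per_factor
        ]
        if not candidates:
            entry["status"] = "floor_reached"
            history.append(entry)
            return fmap, history
        cand = agg.loc[[c for c in candidates if c in agg.index]]
        cand = cand.dropna(subset=["statistic"])
        if cand.empty:
            entry["status"] = "floor_reached"
            history.append(entry)
            return fmap, history
        # max statistic; ties by item label order (index is already sorted)
        worst = cand["statistic"].idxmax()
        entry["removed"] = worst
        entry["mi"] = agg
        entry["failing_level"] = level
        history.append(entry)
        fmap.pop(worst)


# --------------------------------------------------------------------------
# stress scoring
# --------------------------------------------------------------------------

def score_stress(likert, retained_items=None, item_factor_map=None):
    """PS/ED/SE totals and their reduced counterparts.

    Self-Efficacy items are positively worded, so they are reverse-scored
    (4 - response) before entering the PS totals; the SE factor score
    itself sums the raw responses. ``rRatio = rED / rSE`` is missing when
    rSE is zero. Any missing item response propagates to the scores that
    use it.
    """
    fmap = item_factor_map or DEFAULT_ITEM_FACTOR_MAP
    items = [c for c in likert.columns if c in fmap]
    retained = sorted(retained_items) if retained_items is not None else items
    vals = likert[items].astype(float)

    def _scores(subset, prefix):
        ed = [i for i in subset if fmap[i] == "ED"]
        se = [i for i in subset if fmap[i] == "SE"]
        ed_sum = vals[ed].sum(axis=1, min_count=len(ed))
        se_sum = vals[se].sum(axis=1, min_count=len(se))
        ps = ed_sum + (4.0 * len(se) - se_sum)
        return {f"{prefix}PS": ps, f"{prefix}ED": ed_sum, f"{prefix}SE": se_sum}

    out = pd.DataFrame(index=likert.index)
    for name, col in _scores(items, "").items():
        out[name] = col
    for name, col in _scores(retained, "r").items():
        out[name] = col
    out["rRatio"] = out["rED"] / out["rSE"].replace(0, np.nan)
    return out


# --------------------------------------------------------------------------
# exploratory factor analysis
# --------------------------------------------------------------------------

def polychoric_matrix(likert_values: pd.DataFrame) -> pd.DataFrame:
    """Two-step polychoric correlation matrix for ordinal items.

    Thresholds come from inverse-normal marginal cumulative proportions;
    each pairwise correlation maximizes the bivariate-normal cell
    likelihood. Items with a single observed category get NaN estimates
    (flagged by warning).
    """
    items = list(likert_values.columns)
    X = likert_values.to_numpy(int)
    n, p = X.shape
    taus, degenerate = [], []
    for j in range(p):
        levels = np.unique(X[:, j])
        if len(levels) < 2:
            degenerate.append(items[j])
            taus.append(None)
            continue
        cats = np.arange(X[:, j].min(), X[:, j].max() + 1)
        cum = np.array([(X[:, j] <= c).mean() for c in cats[:-1]])
        tau = stats.norm.ppf(np.clip(cum, 1e-8, 1 - 1e-8))
        taus.append((cats, np.concatenate([[-8.0], tau, [8.0]])))
    if degenerate:
        warnings.warn(f"single-category items, estimates undefined: {degenerate}")

    def cell_probs(ti, tj, rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        a, b = np.meshgrid(ti, tj, indexing="ij")
        pts = np.column_stack([a.ravel(), b.ravel()])
        cdf = stats.multivariate_normal(cov=cov).cdf(pts).reshape(a.shape)
        P = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        return np.clip(P, 1e-12, None)

    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if taus[i] is None or taus[j] is None:
                R[i, j] = R[j, i] = np.nan
                continue
            cats_i, ti = taus[i]
            cats_j, tj = taus[j]
            tabs = np.zeros((len(cats_i), len(cats_j)))
            for a, ci in enumerate(cats_i):
                for b, cj in enumerate(cats_j):
                    tabs[a, b] = np.sum((X[:, i] == ci) & (X[:, j] == cj))

            def nll(rho):
                return -np.sum(tabs * np.log(cell_probs(ti, tj, rho)))

            res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999),
                                           method="bounded",
                                           options={"xatol": 1e-4})
            R[i, j] = R[j, i] = res.x
    return pd.DataFrame(R, index=items, columns=items)


def parallel_analysis(corr, n_obs, n_reps=200, quantile=0.95, seed=0):
    """Retained-factor count: observed correlation eigenvalues vs. the
    chosen quantile of eigenvalues from random normal data of the same
    shape."""
    if n_reps < 20:
        warnings.warn("parallel analysis with fewer than 20 replicates is unstable")
    R = np.asarray(corr, float)
    p = R.shape[0]
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    sim = np.empty((n_reps, p))
    for r in range(n_reps):
        Z = rng.standard_normal((n_obs, p))
        sim[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    ref = np.quantile(sim, quantile, axis=0)
    k = 0
    for j in range(p):
        if obs[j] > ref[j]:
            k += 1
        else:
            break
    return k


def cronbach_alpha(values) -> float:
    """alpha = k/(k-1) * (1 - sum item variances / variance of the sum)."""
    V = np.asarray(values, float)
    k = V.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least two items")
    total_var = np.var(V.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - V.var(axis=0, ddof=1).sum() / total_var))


def _varimax(L, max_iter=100, tol=1e-8):
    p, k = L.shape
    Rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * (Lr**2).sum(axis=0)) / p)
        )
        Rot = u @ vt
        if s.sum() < var * (1 + tol):
            break
        var = s.sum()
    return L @ Rot, Rot


@dataclass
class EFAResult:
    corr: pd.DataFrame
    n_factors: int
    loadings: pd.DataFrame
    factor_corr: np.ndarray
    uniquenesses: pd.Series
    heywood: bool
    alphas: dict = field(default_factory=dict)


def efa_minres_promax(corr, n_factors, max_iter=2000, promax_power=4) -> EFAResult:
    """Minimum-residual extraction with varimax pre-rotation and an
    oblique Promax transform (default power 4).

    Heywood cases (communality > 1) are flagged and the offending rows
    clipped to unit communality, never silently hidden.
    """
    R = np.asarray(corr, float)
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, n_items)")
    mask = ~np.eye(p, dtype=bool)

    def load_from_psi(psi):
        red = R - np.diag(psi)
        w, V = np.linalg.eigh(red)
        order = np.argsort(w)[::-1][:n_factors]
        return V[:, order] * np.sqrt(np.clip(w[order], 0, None))

    def objective(psi):
        L = load_from_psi(psi)
        resid = R - L @ L.T
        return float(np.sum(resid[mask] ** 2))

    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R + 1e-8 * np.eye(p)))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(objective, psi0, method="L-BFGS-B",
                            bounds=[(1e-3, 1.0)] * p,
                            options={"maxiter": max_iter})
    L = load_from_psi(res.x)
    comm = (L**2).sum(axis=1)
    heywood = bool(np.any(comm > 1 + 1e-6))
    if heywood:
        warnings.warn("Heywood case: communalities > 1, loadings clipped")
        over = comm > 1
        L[over] = L[over] / np.sqrt(comm[over])[:, None]

    if n_factors > 1:
        V, _ = _varimax(L)
        P = np.abs(V) ** promax_power * np.sign(V)
        U = np.linalg.lstsq(V, P, rcond=None)[0]
        d = np.diag(np.linalg.inv(U.T @ U))
        U = U * np.sqrt(d)
        Lp = V @ U
        Phi = np.linalg.inv(U.T @ U)
        dd = np.sqrt(np.diag(Phi))
        Phi = Phi / np.outer(dd, dd)
    else:
        Lp, Phi = L, np.eye(1)

    idx = list(corr.index) if isinstance(corr, pd.DataFrame) else list(range(p))
    return EFAResult(
        corr=pd.DataFrame(R, index=idx, columns=idx),
        n_factors=n_factors,
        loadings=pd.DataFrame(Lp, index=idx,
                              columns=[f"F{i+1}" for i in range(n_factors)]),
        factor_corr=Phi,
        uniquenesses=pd.Series(res.x, index=idx),
        heywood=heywood,
    )
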