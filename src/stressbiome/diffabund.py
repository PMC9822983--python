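"""Zero-inflated Gaussian (ZIG) differential abundance.

Models each feature's log2(count + 1) as a mixture of a point mass at
zero -- with mixing probability a logistic function of log2 library size,
capturing depth-driven dropout -- and a Gaussian whose mean is a linear
function of the design plus a log2 CSS-factor offset. Fit by EM:
posterior zero responsibilities in the E-step, weighted least squares and
a logistic refit in the M-step.

With no zeros in a feature the mixture collapses and the coefficients
equal plain OLS estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats, special
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests


def bh_fdr(p):
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _weighted_logistic(z, x, max_iter=25):
    """Fit z ~ logistic(g0 + g1*x) to fractional responses by Newton
    iterations; the slope is capped at 0 so the zero probability is
    monotone non-increasing in log depth."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.array([special.logit(np.clip(z.mean(), 1e-6, 1 - 1e-6)), 0.0])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (z - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    if beta[1] > 0:
        beta = np.array([special.logit(np.clip(z.mean(), 1e-6, 1 - 1e-6)), 0.0])
    return beta


class ZeroInflatedGaussianRegressor(BaseEstimator, RegressorMixin):
    """EM fit of the zero-inflated Gaussian model for one feature.

    Parameters
    ----------
    tol : float
        Convergence threshold on the max absolute parameter change.
    max_iter : int
        EM iteration cap; non-convergence is flagged, last iterate kept.

    Attributes
    ----------
    coef_ : ndarray, Gaussian-mean coefficients for the design columns.
    se_, tvalues_, pvalues_ : per-coefficient inference (t distribution
        with effective df = sum of Gaussian responsibilities - rank).
    zero_coef_ : (intercept, slope) of the logistic zero model.
    responsibilities_ : posterior point-mass membership per sample.
    sigma_ : Gaussian residual SD.
    converged_, n_iter_ : EM diagnostics.
    """

    def __init__(self, tol=1e-6, max_iter=100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, offset=None, depth=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, k = X.shape
        if np.linalg.matrix_rank(X) < k:
            raise ValueError("design matrix is rank deficient")
        offset = np.zeros(n) if offset is None else np.asarray(offset, float)
        if depth is None:
            depth = np.full(n, 2.0 ** offset.mean())
        ldepth = np.log2(np.asarray(depth, float))
        yz = y - offset
        is_zero = y == 0

        if is_zero.all():
            warnings.warn("all-zero feature: Gaussian component undefined")
            self.coef_ = np.full(k, np.nan)
            self.se_ = np.full(k, np.nan)
            self.tvalues_ = np.full(k, np.nan)
            self.pvalues_ = np.full(k, np.nan)
            self.converged_ = False
            self.degenerate_ = True
            self.n_iter_ = 0
            return self
        self.degenerate_ = False

        z = np.where(is_zero, 0.5, 0.0)
        beta = np.linalg.lstsq(X, yz, rcond=None)[0]
        sigma = max(np.std(yz - X @ beta), 1e-3)
        gamma = np.array([0.0, 0.0])
        converged = False
        for it in range(1, self.max_iter + 1):
            # E-step
            pi = special.expit(gamma[0] + gamma[1] * ldepth)
            dens = stats.norm.pdf(-offset, loc=X @ beta, scale=sigma)
            z_new = np.where(is_zero, pi / np.clip(pi + (1 - pi) * dens, 1e-300, None), 0.0)
            # M-step
            w = 1.0 - z_new
            sw = np.sqrt(np.clip(w, 1e-12, None))
            beta_new = np.linalg.lstsq(X * sw[:, None], yz * sw, rcond=None)[0]
            resid = yz - X @ beta_new
            sigma_new = np.sqrt(np.sum(w * resid**2) / max(np.sum(w), 1e-12))
            sigma_new = max(sigma_new, 1e-4)
            gamma_new = _weighted_logistic(z_new, ldepth)
            delta = max(
                np.max(np.abs(beta_new - beta)),
                abs(sigma_new - sigma),
                np.max(np.abs(gamma_new - gamma)),
            )
            beta, sigma, gamma, z = beta_new, sigma_new, gamma_new, z_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("ZIG EM did not converge; returning last iterate")

        w = 1.0 - z
        XtWX = (X * w[:, None]).T @ X
        cov = np.linalg.inv(XtWX) * sigma**2
        df_eff = max(np.sum(w) - k, 1.0)
        # small-sample variance rescale to the effective df
        cov = cov * np.sum(w) / df_eff
        self.coef_ = beta
        self.se_ = np.sqrt(np.diag(cov))
        self.tvalues_ = beta / self.se_
        self.pvalues_ = 2 * stats.t.sf(np.abs(self.tvalues_), df_eff)
        self.sigma_ = sigma
        self.zero_coef_ = gamma
        self.responsibilities_ = z
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def predict(self, X, offset=None):
        X = np.asarray(X, float)
        mu = X @ self.coef_
        return mu + (0 if offset is None else np.asarray(offset, float))


def zig_fit(y, X, offset=None, depth=None, **kwargs):
    """Fit one feature; y is log2(count+1), X the design, offset the
    log2 CSS factor. Returns the fitted estimator."""
    return ZeroInflatedGaussianRegressor(**kwargs).fit(X, y, offset=offset, depth=depth)


def associate(
    counts: pd.DataFrame,
    targets: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    offset: pd.Series | None = None,
    min_prevalence: float = 0.10,
) -> pd.DataFrame:
    """Per-feature, per-target ZIG associations with BH correction.

    ``counts`` are raw counts (samples x features); each target column is
    modeled as the last design column after the covariates. Features
    detected in fewer than ``min_prevalence`` of samples are skipped
    (the mixture is unidentifiable for ultra-rare features). q-values are
    BH-adjusted across features within each target; significance tiers
    are q < 0.05 and q < 0.01.

    Output columns: feature, target, beta, se, t, p, q, n_nonzero, tier.
    """
    depth = counts.sum(axis=1).to_numpy(float)
    y_all = np.log2(counts.to_numpy(float) + 1.0)
    n = len(counts)
    off = None if offset is None else offset.loc[counts.index].to_numpy(float)

    cov_mat = [np.ones((n, 1))]
    if covariates is not None:
        for c in covariates.columns:
            cov_mat.append(_encode(covariates[c]))
    base = np.hstack(cov_mat)

    frames = []
    prev = (counts > 0).mean(axis=0)
    modeled = [f for f in counts.columns if prev[f] >= min_prevalence]
    for tcol in targets.columns:
        tv = targets[tcol].to_numpy(float)
        if np.nanstd(tv) == 0:
            raise ValueError(f"constant target {tcol!r}")
        keep = ~np.isnan(tv)
        X = np.hstack([base[keep], tv[keep, None]])
        rows = []
        for f in modeled:
            fitr = ZeroInflatedGaussianRegressor().fit(
                X, y_all[keep, counts.columns.get_loc(f)],
                offset=None if off is None else off[keep], depth=depth[keep],
            )
            rows.append(dict(
                feature=f, target=tcol,
                beta=fitr.coef_[-1], se=fitr.se_[-1],
                t=fitr.tvalues_[-1], p=fitr.pvalues_[-1],
                n_nonzero=int((counts[f].to_numpy()[keep] > 0).sum()),
                converged=fitr.converged_,
            ))
        res = pd.DataFrame(rows)
        ok = res["p"].notna()
        res["q"] = np.nan
        res.loc[ok, "q"] = bh_fdr(res.loc[ok, "p"].to_numpy())
        res["tier"] = np.select(
            [res["q"] < 0.01, res["q"] < 0.05], ["**", "*"], default=""
        )
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def _encode(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.get_dummies(col, drop_first=True).to_numpy(float)
    return col.to_numpy(float)[:, None]
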