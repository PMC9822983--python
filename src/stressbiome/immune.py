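"""Serum cytokine/chemokine analyses: covariate-adjusted log-linear
models, partial Spearman correlation structure, and k-means participant
clustering."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from stressbiome.diffabund import bh_fdr


def handle_detection_limit(panel: pd.DataFrame, limits=None) -> pd.DataFrame:
    """Impute below-detection values at limit/sqrt(2) (flagged via attrs)."""
    out = panel.copy()
    flags = pd.DataFrame(False, index=panel.index, columns=panel.columns)
    if limits is not None:
        for a, lim in limits.items():
            low = out[a] < lim
            out.loc[low, a] = lim / np.sqrt(2)
            flags[a] = low
    out.attrs["below_detection"] = flags
    return out


def adjusted_linear_models(panel: pd.DataFrame, predictor: pd.Series,
                           adjust: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-analyte OLS of log concentration on a predictor plus adjusters
    (BMI and recruitment site in the study design), with BH q-values
    across analytes.

    Categorical predictors use treatment coding with the largest level as
    reference; multi-level predictors report the F-test p over their
    contrasts and the first contrast's coefficient.
    """
    if predictor.nunique() < 2:
        raise ValueError("constant predictor")
    logp = np.log(panel)
    n = len(panel)
    blocks = [np.ones((n, 1))]
    if adjust is not None:
        for c in adjust.columns:
            blocks.append(_encode(adjust[c]))
    base = np.hstack(blocks)
    pred = _encode(predictor, largest_ref=True)
    X = np.hstack([base, pred])
    rows = []
    for a in panel.columns:
        yv = logp[a].to_numpy(float)
        full = sm.OLS(yv, X).fit()
        if pred.shape[1] == 1:
            beta, p = full.params[-1], full.pvalues[-1]
        else:
            restr = sm.OLS(yv, base).fit()
            f = ((restr.ssr - full.ssr) / pred.shape[1]) / full.mse_resid
            p = float(stats.f.sf(f, pred.shape[1], full.df_resid))
            beta = full.params[-pred.shape[1]]
        rows.append(dict(analyte=a, beta=float(beta), p=float(p)))
    res = pd.DataFrame(rows)
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res.set_index("analyte")


def partial_spearman(panel: pd.DataFrame, control: pd.DataFrame | None = None):
    """Analyte x analyte partial Spearman correlations, controlling for
    covariates (e.g. BMI), with BH q-values over the upper-triangle pairs.

    Ranks (average for ties) are residualized on the controls' ranks and
    correlated by Pearson; with an empty control set this equals plain
    Spearman exactly. Constant analytes give NaN rows (flagged).

    Returns (rho, p, q) DataFrames.
    """
    n = len(panel)
    k = 0 if control is None else control.shape[1]
    if n <= k + 2:
        raise ValueError("not enough observations for the control set")
    R = panel.rank()
    const = [a for a in panel.columns if panel[a].nunique() < 2]
    if const:
        warnings.warn(f"constant analytes, correlations undefined: {const}")
    if control is not None and k > 0:
        C = np.column_stack([np.ones(n)] +
                            [control[c].rank().to_numpy(float) for c in control.columns])
        proj = C @ np.linalg.pinv(C)
        Rv = R.to_numpy(float) - proj @ R.to_numpy(float)
    else:
        Rv = R.to_numpy(float) - R.to_numpy(float).mean(axis=0)
    sd = Rv.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Rv.T @ Rv) / n / np.outer(sd, sd)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1, 1)
    for a in const:
        i = panel.columns.get_loc(a)
        rho[i, :] = rho[:, i] = np.nan
        rho[i, i] = np.nan

    dof = n - 2 - k
    iu = np.triu_indices_from(rho, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho[iu] * np.sqrt(dof / (1 - rho[iu] ** 2))
    pv = 2 * stats.t.sf(np.abs(tstat), dof)
    ok = np.isfinite(pv)
    qv = np.full_like(pv, np.nan)
    qv[ok] = bh_fdr(pv[ok])
    pmat = np.full_like(rho, np.nan)
    qmat = np.full_like(rho, np.nan)
    pmat[iu] = pv
    qmat[iu] = qv
    pmat = np.where(np.isnan(pmat), pmat.T, pmat)
    qmat = np.where(np.isnan(qmat), qmat.T, qmat)
    cols = panel.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pmat, index=cols, columns=cols),
            pd.DataFrame(qmat, index=cols, columns=cols))


def kmeans_participants(panel: pd.DataFrame, k_range=range(2, 7), seed=0,
                        n_init=20):
    """Cluster participants on log-scaled, per-analyte standardized
    profiles; k chosen by maximum mean silhouette over ``k_range``.

    Returns (assignment Series, {k: silhouette}, chosen k).
    """
    X = np.log(panel.to_numpy(float))
    sd = X.std(axis=0)
    if np.all(sd < 1e-12) or len(np.unique(X, axis=0)) < 2:
        warnings.warn("degenerate panel: participants indistinguishable")
        return pd.Series(0, index=panel.index, name="cluster"), {}, 1
    X = (X - X.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
    profile = {}
    best = None
    for k in k_range:
        if k >= len(panel):
            raise ValueError("k must be smaller than the number of participants")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        sil = float(silhouette_score(X, km.labels_))
        profile[k] = sil
        if best is None or sil > profile[best[0]]:
            best = (k, km.labels_)
    k_opt, labels = best
    return pd.Series(labels, index=panel.index, name="cluster"), profile, k_opt


def _encode(col: pd.Series, largest_ref=False) -> np.ndarray:
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        if largest_ref:
            ref = col.value_counts().idxmax()
            levels = [ref] + [l for l in sorted(col.unique()) if l != ref]
            cat = pd.Categorical(col, categories=levels)
            return pd.get_dummies(cat, drop_first=True).to_numpy(float)
        return pd.get_dummies(col, drop_first=True).to_numpy(float)
    return col.to_numpy(float)[:, None]
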