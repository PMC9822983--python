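"""ASV-table quality control, CSS normalization, diversity, volatility and
multi-term PERMANOVA.

Counts tables are pandas DataFrames with samples as rows and ASV
identifiers as columns (BIOM orientation for flat files); taxonomy is a
per-ASV DataFrame carrying at least ``genus`` and ``family`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha
from sklearn.base import BaseEstimator, TransformerMixin


# --------------------------------------------------------------------------
# QC filtering
# --------------------------------------------------------------------------

@dataclass
class QCAudit:
    dropped_samples: list
    dropped_asvs: list

    def summary(self) -> pd.DataFrame:
        rows = [{"id": s, "kind": "sample", "rule": r} for s, r in self.dropped_samples]
        rows += [{"id": a, "kind": "asv", "rule": r} for a, r in self.dropped_asvs]
        return pd.DataFrame(rows, columns=["id", "kind", "rule"])


def qc_filter(
    counts: pd.DataFrame,
    controls: set | None = None,
    lengths: pd.Series | None = None,
    min_reads: int = 5,
    length_range: tuple = (251, 254),
    min_rel_abund: float = 0.01,
    min_count: int = 10,
    contaminant_rule: str = "control_based",
    control_prevalence: float = 0.9,
    sample_prevalence: float = 0.9,
):
    """Sequential ASV-table QC with a per-removal audit trail.

    Order of operations:

    1. drop samples with total reads < ``min_reads``;
    2. drop ASVs whose sequence length falls outside ``length_range``
       (inclusive), when lengths are provided;
    3. contaminant removal -- default ``"control_based"``: ASVs detected in
       at least ``control_prevalence`` of the negative-control samples AND
       at higher mean relative abundance in controls than in study samples.
       ``"literal_prevalence"`` instead drops ASVs not present in at least
       ``sample_prevalence`` of the study samples (a far more aggressive
       rule, retained behind this explicit flag);
    4. drop ASVs whose relative abundance is below ``min_rel_abund`` in
       every sample AND whose count is below ``min_count`` in every sample.

    Returns (filtered counts restricted to study samples, QCAudit).
    """
    controls = set(controls or ())
    if controls - set(counts.index):
        raise ValueError("controls must be rows of the count table")
    dropped_samples, dropped_asvs = [], []

    totals = counts.sum(axis=1)
    low = totals[totals < min_reads].index
    dropped_samples += [(s, f"total reads < {min_reads}") for s in low]
    counts = counts.drop(index=low)
    controls = controls - set(low)

    if lengths is not None:
        lo, hi = length_range
        bad = lengths.index[(lengths < lo) | (lengths > hi)]
        bad = [a for a in bad if a in counts.columns]
        dropped_asvs += [(a, f"length outside [{lo},{hi}]") for a in bad]
        counts = counts.drop(columns=bad)

    study = counts.drop(index=[s for s in controls if s in counts.index])
    if controls and contaminant_rule == "control_based":
        ctrl = counts.loc[sorted(controls)]
        prev_ctrl = (ctrl > 0).mean(axis=0)
        rel_ctrl = ctrl.div(ctrl.sum(axis=1).replace(0, 1), axis=0).mean(axis=0)
        rel_study = study.div(study.sum(axis=1).replace(0, 1), axis=0).mean(axis=0)
        contam = prev_ctrl.index[(prev_ctrl >= control_prevalence)
                                 & (rel_ctrl > rel_study)]
        dropped_asvs += [(a, "contaminant (control-based)") for a in contam]
        study = study.drop(columns=contam)
    elif contaminant_rule == "literal_prevalence":
        prev = (study > 0).mean(axis=0)
        contam = prev.index[prev < sample_prevalence]
        dropped_asvs += [(a, "contaminant (literal prevalence)") for a in contam]
        study = study.drop(columns=contam)
    elif contaminant_rule != "control_based":
        raise ValueError(f"unknown contaminant rule {contaminant_rule!r}")

    rel = study.div(study.sum(axis=1).replace(0, 1), axis=0)
    rare = study.columns[(rel.max(axis=0) < min_rel_abund)
                         & (study.max(axis=0) < min_count)]
    dropped_asvs += [(a, f"rel<{min_rel_abund} and count<{min_count} everywhere")
                     for a in rare]
    study = study.drop(columns=rare)

    audit = QCAudit(dropped_samples, dropped_asvs)
    if study.shape[0] == 0 or study.shape[1] == 0:
        raise ValueError(f"table empty after QC; audit: {audit.summary()}")
    return study, audit


# --------------------------------------------------------------------------
# CSS normalization
# --------------------------------------------------------------------------

class CSSNormalizer(BaseEstimator, TransformerMixin):
    """Cumulative sum scaling for marker-gene count tables.

    Each sample's scaling factor is the sum of its counts up to a chosen
    quantile ``l`` of the sample's nonzero counts. ``l`` is selected
    adaptively: the smallest grid quantile at which the median absolute
    relative deviation of the quantile-truncated sums across samples
    exceeds ``instability_threshold``, floored at the median (l = 0.5).
    Normalized value = count / factor * ``scale``.

    Attributes
    ----------
    quantile_ : float
        Chosen quantile l.
    scaling_factors_ : pd.Series
        Per-sample CSS factors (strictly positive).
    """

    def __init__(self, quantile=None, instability_threshold=0.1, scale=1000.0):
        self.quantile = quantile
        self.instability_threshold = instability_threshold
        self.scale = scale

    @staticmethod
    def _truncated_sums(counts: np.ndarray, l: float) -> np.ndarray:
        out = np.empty(counts.shape[0])
        for i, row in enumerate(counts):
            pos = row[row > 0]
            if len(pos) == 0:
                raise ValueError("all-zero sample; run QC first")
            q = np.quantile(pos, l)
            out[i] = row[(row > 0) & (row <= q)].sum()
        return out

    def fit(self, X, y=None):
        counts = np.asarray(X, float)
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero sample; run QC first")
        if self.quantile is not None:
            l = self.quantile
        else:
            grid = np.arange(0.05, 1.0, 0.05)
            l = 0.5
            for cand in grid:
                s = self._truncated_sums(counts, cand)
                med = np.median(s)
                if med > 0:
                    mad_rel = np.median(np.abs(s - med)) / med
                    if mad_rel > self.instability_threshold:
                        l = cand
                        break
            l = max(l, 0.5)
        self.quantile_ = float(l)
        factors = self._truncated_sums(counts, l)
        factors = np.maximum(factors, 1.0)
        idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(factors))
        self.scaling_factors_ = pd.Series(factors, index=idx, name="css_factor")
        return self

    def transform(self, X):
        factors = self.scaling_factors_.to_numpy()
        norm = np.asarray(X, float) / factors[:, None] * self.scale
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(norm, index=X.index, columns=X.columns)
        return norm

    def log2_offsets(self) -> pd.Series:
        """log2 CSS factors, the per-sample offset for downstream models."""
        return np.log2(self.scaling_factors_).rename("log2_css_factor")


def css_normalize(counts: pd.DataFrame, quantile=None):
    """Functional wrapper: returns (normalized table, css factors, quantile)."""
    norm = CSSNormalizer(quantile=quantile).fit(counts)
    return norm.transform(counts), norm.scaling_factors_, norm.quantile_


# --------------------------------------------------------------------------
# diversity
# --------------------------------------------------------------------------

def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed richness, bias-corrected Chao1, Shannon (nats), inverse
    Simpson and ACE per sample, from raw (unnormalized) counts."""
    vals = np.asarray(counts, float)
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("empty sample")
    rows = []
    for row in vals.astype(int):
        rows.append(dict(
            observed=int(skbio_alpha.sobs(row)),
            chao1=float(skbio_alpha.chao1(row, bias_corrected=True)),
            shannon=float(skbio_alpha.shannon(row, base=np.e)),
            inv_simpson=float(skbio_alpha.enspie(row)),
            ace=float(skbio_alpha.ace(row, rare_threshold=10)),
        ))
    return pd.DataFrame(rows, index=counts.index)


def rarefy(counts: pd.DataFrame, depth: int, seed=0) -> pd.DataFrame:
    """Seeded single-draw subsampling without replacement; samples below
    ``depth`` are dropped with a warning."""
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    keep = totals[totals >= depth].index
    if len(keep) < len(counts):
        warnings.warn(f"dropping {len(counts) - len(keep)} samples below depth {depth}")
    out = {}
    for s in keep:
        row = counts.loc[s].to_numpy(int)
        out[s] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame.from_dict(out, orient="index", columns=counts.columns)


def bray_curtis(matrix: pd.DataFrame, rarefy_depth=None, seed=0) -> pd.DataFrame:
    """Bray-Curtis dissimilarity BC(u,v) = sum|u_i - v_i| / sum(u_i + v_i)."""
    if (np.asarray(matrix) < 0).any():
        raise ValueError("negative entries")
    if rarefy_depth is not None:
        matrix = rarefy(matrix, rarefy_depth, seed)
    D = squareform(pdist(np.asarray(matrix, float), metric="braycurtis"))
    return pd.DataFrame(np.nan_to_num(D), index=matrix.index, columns=matrix.index)


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if col.nunique() < 2:
        raise ValueError(f"constant term {term!r}")
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.get_dummies(col, drop_first=True).to_numpy(float)
    return col.to_numpy(float)[:, None]


def permanova(dist, design: pd.DataFrame, terms: list, n_perm=999, seed=0) -> pd.DataFrame:
    """Sequential (type-I) PERMANOVA on a distance matrix.

    The Gower-centered matrix G = -0.5 J D^2 J is partitioned along the
    nested sequence of design projections in ``terms`` order; p-values
    come from permutation of the raw observations (rows of D), default
    999 permutations, seeded.
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    if len(design) != n:
        raise ValueError("design rows must match distance rows")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J

    X_blocks = [np.ones((n, 1))]
    hats, dfs = [], []
    rank_prev = 1
    for term in terms:
        X_blocks.append(_design_columns(design, term))
        X = np.hstack(X_blocks)
        rank = np.linalg.matrix_rank(X)
        hats.append(X @ np.linalg.pinv(X))
        dfs.append(rank - rank_prev)
        rank_prev = rank
    H_full = hats[-1]
    df_res = n - rank_prev
    H0 = np.ones((n, n)) / n

    def term_stats(Gm):
        tr_prev = float(np.sum(H0 * Gm))
        ss_terms = []
        for H in hats:
            tr = float(np.sum(H * Gm))
            ss_terms.append(tr - tr_prev)
            tr_prev = tr
        ss_res = float(np.trace(Gm)) - float(np.sum(H_full * Gm))
        F = np.array([(ss / df) / (ss_res / df_res) for ss, df in zip(ss_terms, dfs)])
        return np.array(ss_terms), ss_res, F

    ss_obs, _, F_obs = term_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, _, F_p = term_stats(G[np.ix_(p, p)])
        exceed += F_p >= F_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)
    total_ss = float(np.trace(G))
    return pd.DataFrame({
        "df": dfs, "SS": ss_obs, "R2": ss_obs / total_ss,
        "pseudo_F": F_obs, "p": pvals,
    }, index=pd.Index(terms, name="term"))


# --------------------------------------------------------------------------
# volatility
# --------------------------------------------------------------------------

def volatility(dist: pd.DataFrame, metadata: pd.DataFrame):
    """Per-participant T2->T3 ecological distance, plus an OLS fit of
    volatility on the between-visit gestational-week difference adjusted
    for cohort.

    Returns (per-participant DataFrame, statsmodels OLS results).
    """
    pairs = []
    for pid, sub in metadata.groupby("participant"):
        tri = dict(zip(sub["trimester"], sub.index))
        if "T2" in tri and "T3" in tri and tri["T2"] in dist.index and tri["T3"] in dist.index:
            w = sub.set_index("trimester")["gestational_weeks"]
            pairs.append(dict(participant=pid,
                              volatility=float(dist.loc[tri["T2"], tri["T3"]]),
                              delta_weeks=float(w["T3"] - w["T2"]),
                              site=sub["site"].iloc[0]))
    if not pairs:
        raise ValueError("no participants with both T2 and T3 samples")
    df = pd.DataFrame(pairs).set_index("participant")
    X = pd.DataFrame({"delta_weeks": df["delta_weeks"]})
    X = pd.concat([X, pd.get_dummies(df["site"], drop_first=True, dtype=float)], axis=1)
    X = sm.add_constant(X)
    model = sm.OLS(df["volatility"], X).fit()
    return df, model
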