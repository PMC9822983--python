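"""SparCC co-abundance inference with bootstrap edge calibration, and
assembly of the integrated ASV/genus - cytokine - stress network.

SparCC estimates correlations between components of compositional count
data from log-ratio variances: with t_ij = var(log(x_i/x_j)) and basis
variances w_i solved from the sparsity-approximated linear system,

    r_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).

Edge significance uses a permutation bootstrap that scrambles each
taxon's counts across samples (destroying co-abundance, preserving
marginals): an edge is significant when |r_obs| exceeds ``multiplier``
bootstrap SDs of r AND the corresponding z-score condition holds, with
z = r / SD_boot(r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class SparccResult:
    correlations: pd.DataFrame
    basis_variances: pd.Series
    excluded_pairs: list


class SparCC(BaseEstimator):
    """SparCC compositional correlation estimator.

    Parameters
    ----------
    n_inferences : int
        Dirichlet resampling repetitions; the final estimate is their
        median.
    resample : bool
        If False, skip the Dirichlet resampling and use the posterior
        mean fractions (counts+1)/(total+D) once -- deterministic and
        exactly invariant to taxon order.
    exclusion_threshold : float
        Per-round exclusion: the most correlated remaining pair is
        removed from the linear system while its |r| exceeds this.
    max_exclusion_rounds : int
        Cap on excluded pairs per inference.

    Attributes
    ----------
    correlations_ : DataFrame, symmetric, in [-1, 1].
    basis_variances_ : Series (median over inferences).
    """

    def __init__(self, n_inferences=20, exclusion_threshold=0.1,
                 max_exclusion_rounds=10, seed=0, resample=True):
        self.n_inferences = n_inferences
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.seed = seed
        self.resample = resample

    def fit(self, counts, y=None):
        C = np.asarray(counts, float)
        n, D = C.shape
        if D < 4:
            raise ValueError("SparCC needs at least 4 components")
        rng = np.random.default_rng(self.seed)
        rs, ws = [], []
        excluded_all = []
        n_inf = self.n_inferences if self.resample else 1
        for _ in range(n_inf):
            if self.resample:
                frac = rng.gamma(C + 1.0)
                frac /= frac.sum(axis=1, keepdims=True)
            else:
                frac = (C + 1.0) / (C + 1.0).sum(axis=1, keepdims=True)
            L = np.log(frac)
            cov = np.cov(L, rowvar=False)
            v = np.diag(cov)
            T = v[:, None] + v[None, :] - 2 * cov
            r, w, excl = self._basis_corr(T, D)
            rs.append(r)
            ws.append(w)
            excluded_all.append(excl)
        self.correlations_ = np.median(rs, axis=0)
        np.fill_diagonal(self.correlations_, 1.0)
        self.basis_variances_ = np.median(ws, axis=0)
        self.excluded_pairs_ = excluded_all
        if isinstance(counts, pd.DataFrame):
            self.feature_names_ = list(counts.columns)
        else:
            self.feature_names_ = list(range(D))
        return self

    def _basis_corr(self, T, D):
        M = np.full((D, D), 1.0) + np.diag(np.full(D, D - 2.0))
        t_row = T.sum(axis=1)
        excluded = []
        r = None
        for _ in range(self.max_exclusion_rounds + 1):
            try:
                w2 = np.linalg.solve(M, t_row)
            except np.linalg.LinAlgError:
                warnings.warn("singular SparCC system after exclusions")
                break
            w2 = np.clip(w2, 1e-12, None)
            w = np.sqrt(w2)
            r = (w2[:, None] + w2[None, :] - T) / (2.0 * np.outer(w, w))
            r = np.clip(r, -1.0, 1.0)
            a = np.abs(r.copy())
            np.fill_diagonal(a, 0.0)
            for i, j in excluded:
                a[i, j] = a[j, i] = 0.0
            i, j = np.unravel_index(np.argmax(a), a.shape)
            if a[i, j] <= self.exclusion_threshold or len(excluded) >= self.max_exclusion_rounds:
                break
            excluded.append((min(i, j), max(i, j)))
            M[i, i] -= 1.0
            M[j, j] -= 1.0
            M[i, j] -= 1.0
            M[j, i] -= 1.0
            t_row[i] -= T[i, j]
            t_row[j] -= T[i, j]
        return r, np.clip(np.linalg.solve(M, t_row), 1e-12, None), excluded

    def result(self) -> SparccResult:
        names = self.feature_names_
        return SparccResult(
            correlations=pd.DataFrame(self.correlations_, index=names, columns=names),
            basis_variances=pd.Series(self.basis_variances_, index=names),
            excluded_pairs=self.excluded_pairs_,
        )


def sparcc(counts, n_inferences=20, exclusion_threshold=0.1,
           max_exclusion_rounds=10, seed=0) -> SparccResult:
    """Functional wrapper returning a :class:`SparccResult`."""
    est = SparCC(n_inferences, exclusion_threshold, max_exclusion_rounds, seed)
    return est.fit(counts).result()


def bootstrap_edges(counts, sparcc_result: SparccResult, n_boot=100,
                    multiplier=3.0, seed=0, **sparcc_kw):
    """Bootstrap edge calibration for a SparCC correlation matrix.

    Each bootstrap permutes every taxon's counts independently across
    samples and reruns SparCC. An edge (i, j) is significant iff

        |r_obs| > multiplier * SD_boot(r)   AND
        |z_obs| > multiplier * SD_boot(z),  z := r / SD_boot(r).

    Returns a DataFrame of upper-triangle edges with r, sd_boot, z and a
    ``significant`` flag.
    """
    if n_boot < 30:
        warnings.warn("fewer than 30 bootstrap iterations: unstable SDs")
    C = np.asarray(counts, float)
    n, D = C.shape
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, D, D))
    for b in range(n_boot):
        perm = np.empty_like(C)
        for j in range(D):
            perm[:, j] = C[rng.permutation(n), j]
        est = SparCC(seed=int(rng.integers(2**31)), **sparcc_kw).fit(perm)
        boot[b] = est.correlations_
    sd_r = boot.std(axis=0, ddof=1)
    sd_r = np.where(sd_r > 1e-12, sd_r, np.nan)
    r_obs = sparcc_result.correlations.to_numpy()
    with np.errstate(invalid="ignore"):
        z_obs = r_obs / sd_r
        z_boot = boot / sd_r[None, :, :]
        sd_z = z_boot.std(axis=0, ddof=1)
    names = list(sparcc_result.correlations.columns)
    iu = np.triu_indices(D, k=1)
    sig = (np.abs(r_obs) > multiplier * sd_r) & (np.abs(z_obs) > multiplier * sd_z)
    return pd.DataFrame({
        "source": [names[i] for i in iu[0]],
        "target": [names[j] for j in iu[1]],
        "r": r_obs[iu],
        "sd_boot": sd_r[iu],
        "z": z_obs[iu],
        "significant": np.nan_to_num(sig[iu].astype(float)).astype(bool),
    })


# --------------------------------------------------------------------------
# integrated network
# --------------------------------------------------------------------------

@dataclass
class IntegratedNetwork:
    graph: nx.Graph
    thresholds: dict = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        rows = [dict(u=u, v=v, **d) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows)

    def node_table(self) -> pd.DataFrame:
        deg = dict(self.graph.degree())
        rows = [dict(id=n, degree=deg[n], **d) for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows)


def build_network(
    sparcc_edges: pd.DataFrame,
    cytokine_corr: pd.DataFrame | None = None,
    cytokine_q: pd.DataFrame | None = None,
    stress_assoc: pd.DataFrame | None = None,
    taxon_cytokine_assoc: pd.DataFrame | None = None,
    node_kinds: dict | None = None,
    annotations: dict | None = None,
    rho_threshold=0.65, cytokine_q_threshold=0.001,
    stress_q_threshold=0.05, taxon_cytokine_q_threshold=0.005,
) -> IntegratedNetwork:
    """Assemble the typed multi-omic network from per-source results.

    Edge admission rules: cytokine-cytokine |rho| > 0.65 and q < 0.001;
    stress-factor edges q < 0.05; taxon-taxon edges are the
    bootstrap-significant SparCC set; taxon-cytokine edges q < 0.005.
    Node kinds: "asv", "cytokine", "stress"; an identifier may carry only
    one kind.
    """
    kinds = dict(node_kinds or {})
    G = nx.Graph()

    def add_node(nid, kind):
        if nid in kinds and kinds[nid] != kind:
            raise ValueError(f"identifier {nid!r} used for both {kinds[nid]} and {kind}")
        kinds[nid] = kind
        ann = (annotations or {}).get(nid, {})
        G.add_node(nid, kind=kind, **ann)

    def add_edge(u, v, w, source):
        if u == v:
            return
        G.add_edge(u, v, weight=float(w), sign=int(np.sign(w)), source=source,
                   significant=True)

    if sparcc_edges is not None and len(sparcc_edges):
        for _, e in sparcc_edges[sparcc_edges["significant"]].iterrows():
            add_node(e["source"], "asv")
            add_node(e["target"], "asv")
            add_edge(e["source"], e["target"], e["r"], "sparcc")

    if cytokine_corr is not None:
        cols = list(cytokine_corr.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rho = cytokine_corr.loc[a, b]
                q = cytokine_q.loc[a, b] if cytokine_q is not None else 0.0
                if np.isfinite(rho) and abs(rho) > rho_threshold and q < cytokine_q_threshold:
                    add_node(a, "cytokine")
                    add_node(b, "cytokine")
                    add_edge(a, b, rho, "spearman")

    if stress_assoc is not None and len(stress_assoc):
        for _, row in stress_assoc.iterrows():
            if row["q"] < stress_q_threshold:
                add_node(row["feature"], "asv")
                add_node(row["target"], "stress")
                add_edge(row["feature"], row["target"], row["beta"], "zig")

    if taxon_cytokine_assoc is not None and len(taxon_cytokine_assoc):
        for _, row in taxon_cytokine_assoc.iterrows():
            if row["q"] < taxon_cytokine_q_threshold:
                add_node(row["feature"], "asv")
                add_node(row["target"], "cytokine")
                add_edge(row["feature"], row["target"], row["beta"], "zig/linear")

    return IntegratedNetwork(G, thresholds=dict(
        rho=rho_threshold, cytokine_q=cytokine_q_threshold,
        stress_q=stress_q_threshold, taxon_cytokine_q=taxon_cytokine_q_threshold))


def modules_and_bridges(net: IntegratedNetwork):
    """Connected components, greedy-modularity communities on |weight|,
    per-node bridge scores and articulation points.

    Bridge score = number of distinct communities among a node's
    neighbors (its own community included if a neighbor shares it).
    """
    G = net.graph
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    H = nx.Graph()
    H.add_nodes_from(G.nodes(data=True))
    for u, v, d in G.edges(data=True):
        H.add_edge(u, v, weight=abs(d.get("weight", 1.0)))
    components = [sorted(c) for c in nx.connected_components(H)]
    communities = [set(c) for c in
                   nx.algorithms.community.greedy_modularity_communities(H, weight="weight")]
    comm_of = {}
    for ci, comm in enumerate(communities):
        for node in comm:
            comm_of[node] = ci
    bridge = {
        n: len({comm_of[nb] for nb in H.neighbors(n)}) for n in H.nodes
    }
    articulation = set(nx.articulation_points(H))
    return dict(components=components, communities=communities,
                bridge_scores=bridge, articulation_points=articulation)


def write_edge_list(net: IntegratedNetwork, path):
    net.edge_table().to_csv(path, sep="\t", index=False)


def write_graphml(net: IntegratedNetwork, path):
    nx.write_graphml(net.graph, path)
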