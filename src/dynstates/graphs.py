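"""Binary graph construction and graph-theory metrics over a threshold sweep.

Connectivity matrices are reduced to undirected, unweighted graphs by
proportional thresholding: the top p% of edges by (signed) weight are kept,
so every graph in a cohort shares the same density and network statistics
are comparable across subjects and states. Four complementary metrics are
computed — global efficiency and assortativity (global integration and
resilience), clustering coefficient and betweenness centrality (local
segregation and centrality) — each across the full threshold grid, then
summarized by the area under the metric-vs-threshold curve (AUC) so no
single density is privileged. Small-worldness against degree-preserving
null graphs verifies the sweep covers the small-world regime.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import ComputationError, InputError

GLOBAL_METRICS = ("global_efficiency", "assortativity", "small_worldness")
LOCAL_METRICS = ("clustering_coeff", "betweenness")


@dataclasses.dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with no self-loops, at a known density."""

    adjacency: np.ndarray
    threshold_pct: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InputError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise InputError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InputError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise InputError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)


def _edge_count(p_pct: float, n: int) -> int:
    # nearest integer, half away from zero ("round half-up" for positives)
    return int(np.floor(p_pct / 100.0 * n * (n - 1) / 2 + 0.5))


def proportional_threshold(
    matrix: np.ndarray, p_pct: float, rank_by_absolute: bool = False
) -> BinaryGraph:
    """Keep the top ``p_pct`` percent of edges by signed weight (ties broken
    by lexicographic pair order) and binarize."""
    if not 0 < p_pct < 100:
        raise InputError(f"threshold percentage must lie in (0, 100), got {p_pct}")
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = m[iu, ju]
    if rank_by_absolute:
        w = np.abs(w)
    keep = _edge_count(p_pct, n)
    # primary key: weight descending; ties: (i, j) ascending — deterministic
    order = np.lexsort((ju, iu, -w))
    sel = order[:keep]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[sel], ju[sel]] = 1
    adj += adj.T
    return BinaryGraph(adj, threshold_pct=p_pct)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs; disconnected
    pairs contribute zero."""
    n = g.n_nodes
    if n < 2:
        raise InputError("global efficiency needs at least 2 nodes")
    d = shortest_path(g.adjacency, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def assortativity(g: BinaryGraph) -> float:
    """Newman's degree assortativity: Pearson correlation of end-point degrees
    across edges (each edge counted in both directions).

    Returns NaN (undefined) when end-point degree variance is zero, e.g. on
    regular graphs.
    """
    if g.n_edges == 0:
        raise ComputationError("assortativity undefined on an edgeless graph")
    deg = g.adjacency.sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    x = np.concatenate([deg[iu], deg[ju]])
    y = np.concatenate([deg[ju], deg[iu]])
    vx = x.var()
    if vx <= 0:
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / vx)


def clustering_coefficients(g: BinaryGraph) -> np.ndarray:
    """Per-node fraction of neighbor pairs that are themselves connected;
    zero by convention for nodes of degree < 2."""
    a = g.adjacency.astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Fraction-of-shortest-paths betweenness centrality, normalized by
    (R-1)(R-2)/2 (Brandes' algorithm with equal-path splitting)."""
    if g.n_nodes < 3:
        raise InputError("betweenness needs at least 3 nodes")
    graph = nx.from_numpy_array(g.adjacency)
    bc = nx.betweenness_centrality(graph, normalized=True)
    return np.array([bc[i] for i in range(g.n_nodes)])


def _char_path_length(adj: np.ndarray) -> float:
    """Characteristic path length on the largest connected component."""
    graph = nx.from_numpy_array(adj)
    comp = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(comp)
    return nx.average_shortest_path_length(sub)


def small_worldness(g: BinaryGraph, n_null: int = 100, seed: int = 0) -> float:
    """Small-world sigma = (C/C_null) / (L/L_null) against degree-preserving
    rewired null graphs.

    C is the mean clustering coefficient, L the characteristic path length on
    the largest connected component; nulls are generated by repeated
    double-edge swaps (10 swaps per edge). Returns NaN with a warning when
    rewiring is impossible (e.g. a star graph admits no degree-preserving
    swap).
    """
    if g.n_edges < 1:
        raise ComputationError("small-worldness needs at least one edge")
    graph = nx.from_numpy_array(g.adjacency)
    comp = max(nx.connected_components(graph), key=len)
    if len(comp) < 4:
        raise ComputationError("largest connected component must have >= 4 nodes")
    c_obs = float(np.mean(clustering_coefficients(g)))
    l_obs = _char_path_length(g.adjacency)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    nswap = 10 * g.n_edges
    for _ in range(n_null):
        h = graph.copy()
        try:
            nx.double_edge_swap(
                h, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXError:
            warnings.warn("degree-preserving rewiring impossible; sigma undefined")
            return float("nan")
        adj_null = nx.to_numpy_array(h, dtype=np.int8)
        c_null.append(float(np.mean(clustering_coefficients(BinaryGraph(adj_null)))))
        l_null.append(_char_path_length(adj_null))
    c_bar, l_bar = float(np.mean(c_null)), float(np.mean(l_null))
    if c_bar == 0 or l_bar == 0:
        warnings.warn("degenerate null ensemble; sigma undefined")
        return float("nan")
    return (c_obs / c_bar) / (l_obs / l_bar)


def metric_auc(values: Sequence[float], thresholds_pct: Sequence[float]) -> float:
    """Trapezoidal AUC over the threshold grid expressed as a fraction.

    Missing (NaN) values are excluded together with their adjacent
    sub-intervals; only segments between consecutive finite points count.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(thresholds_pct, dtype=float) / 100.0
    if len(t) < 2:
        raise InputError("AUC needs at least 2 thresholds")
    if np.any(np.diff(t) <= 0):
        raise InputError("threshold grid must be strictly increasing")
    if len(v) != len(t):
        raise InputError("values and thresholds must align")
    auc = 0.0
    for i in range(len(t) - 1):
        if np.isfinite(v[i]) and np.isfinite(v[i + 1]):
            auc += 0.5 * (v[i] + v[i + 1]) * (t[i + 1] - t[i])
    if not np.isfinite(v).any():
        return float("nan")
    return float(auc)


@dataclasses.dataclass
class GraphMetricProfile:
    """All metrics across the threshold grid plus their AUC summaries."""

    thresholds_pct: tuple[float, ...]
    global_efficiency: np.ndarray          # per threshold
    assortativity: np.ndarray              # per threshold, may contain NaN
    small_worldness: np.ndarray | None     # per threshold, optional
    clustering_coeff: np.ndarray           # thresholds x nodes
    betweenness: np.ndarray                # thresholds x nodes
    auc: dict                              # metric -> scalar or per-node array
    n_undefined_assortativity: int = 0


def assortativity_auc(
    matrix: np.ndarray,
    thresholds_pct: Sequence[float],
    rank_by_absolute: bool = False,
) -> float:
    """Assortativity AUC only — the fast path for resilience screening."""
    vals = []
    for p in thresholds_pct:
        g = proportional_threshold(matrix, p, rank_by_absolute)
        vals.append(assortativity(g) if g.n_edges > 0 else np.nan)
    return metric_auc(vals, thresholds_pct)


def profile_for_matrix(
    matrix: np.ndarray,
    thresholds_pct: Sequence[float],
    n_null: int = 0,
    seed: int = 0,
    rank_by_absolute: bool = False,
) -> GraphMetricProfile:
    """Threshold sweep + all metrics + AUCs for one connectivity matrix.

    Small-worldness (expensive: ``n_null`` rewired graphs per threshold) is
    computed only when ``n_null`` > 0.
    """
    thresholds_pct = tuple(thresholds_pct)
    n = np.asarray(matrix).shape[0]
    eff, asr, cc, bc, sw = [], [], [], [], []
    for i, p in enumerate(thresholds_pct):
        g = proportional_threshold(matrix, p, rank_by_absolute)
        eff.append(global_efficiency(g))
        asr.append(assortativity(g) if g.n_edges > 0 else np.nan)
        cc.append(clustering_coefficients(g))
        bc.append(betweenness(g))
        if n_null > 0:
            try:
                sw.append(small_worldness(g, n_null=n_null, seed=seed + i))
            except ComputationError:
                sw.append(np.nan)
    eff = np.asarray(eff)
    asr = np.asarray(asr)
    cc = np.asarray(cc)
    bc = np.asarray(bc)
    sw_arr = np.asarray(sw) if n_null > 0 else None
    auc = {
        "global_efficiency": metric_auc(eff, thresholds_pct),
        "assortativity": metric_auc(asr, thresholds_pct),
        "clustering_coeff": np.array(
            [metric_auc(cc[:, j], thresholds_pct) for j in range(n)]
        ),
        "betweenness": np.array(
            [metric_auc(bc[:, j], thresholds_pct) for j in range(n)]
        ),
    }
    if sw_arr is not None:
        auc["small_worldness"] = metric_auc(sw_arr, thresholds_pct)
    return GraphMetricProfile(
        thresholds_pct=thresholds_pct,
        global_efficiency=eff,
        assortativity=asr,
        small_worldness=sw_arr,
        clustering_coeff=cc,
        betweenness=bc,
        auc=auc,
        n_undefined_assortativity=int(np.sum(~np.isfinite(asr))),
    )
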