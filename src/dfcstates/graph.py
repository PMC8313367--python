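"""Graph-theory indicators of thresholded connectivity states.

A state matrix (Fisher-Z centroid) is thresholded — entries below tau
(default 0.3, so negative weights are removed too) become 0 — and analysed
either as a binary or a weighted graph.  Segregation is measured by the
clustering coefficient CC_i = 2 t_i / (k_i (k_i - 1)) (t_i triangles around
node i), modularity Q of a Louvain partition, and local efficiency (mean
inverse shortest path inside each node's neighbour-induced subgraph).
Integration is measured by the characteristic path length (mean shortest
path over reachable pairs, with the number of excluded unreachable pairs
reported) and the global efficiency (mean 1/d with 1/inf = 0, well defined
on disconnected graphs).  Hub roles come from the participation coefficient
P_i = 1 - sum_m (k_im / k_i)^2 and the within-module degree z-score
(population-sd standardization of the within-module degree).

Triangle-based and path-based metrics follow the binary-graph formulas, so
they require ``mode="binary"``; degree is reported for both modes (weighted
degree = row sum of surviving weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "ThresholdedGraph",
    "threshold_state",
    "degree",
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "detect_modules",
    "participation_coefficient",
    "within_module_zscore",
    "state_metrics",
]


@dataclass
class ThresholdedGraph:
    """Symmetric zero-diagonal adjacency after thresholding a state matrix."""

    adjacency: np.ndarray
    mode: str  # "binary" or "weighted"
    threshold: float
    sparsity: float  # surviving edges / possible edges

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def threshold_state(
    state_matrix: np.ndarray, tau: float = 0.3, mode: str = "binary"
) -> ThresholdedGraph:
    """Zero all entries strictly below ``tau`` (negatives included).

    In binary mode survivors become 1.  The diagonal is always zeroed.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    a = np.array(state_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("state matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("state matrix must be symmetric")
    a[a < tau] = 0.0
    np.fill_diagonal(a, 0.0)
    if mode == "binary":
        a = (a > 0).astype(float)
    m = a.shape[0]
    sparsity = float((a > 0).sum() / 2 / (m * (m - 1) / 2))
    return ThresholdedGraph(adjacency=a, mode=mode, threshold=tau, sparsity=sparsity)


def _binary(graph: ThresholdedGraph) -> np.ndarray:
    if graph.mode != "binary":
        raise ValueError("metric defined on binary graphs; threshold with mode='binary'")
    return graph.adjacency


def degree(graph: ThresholdedGraph) -> np.ndarray:
    """Binary: neighbour counts; weighted: sum of surviving edge weights."""
    return graph.adjacency.sum(axis=1)


def clustering_coefficient(graph: ThresholdedGraph):
    """Per-node CC_i = 2 t_i / (k_i (k_i - 1)) and its mean; 0 when k_i < 2."""
    a = _binary(graph)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    cc = np.divide(2 * triangles, denom, out=np.zeros_like(k), where=denom > 0)
    return cc, float(cc.mean())


def shortest_path_lengths(graph: ThresholdedGraph) -> np.ndarray:
    """Hop-count distance matrix; unreachable pairs are inf, d_ii = 0."""
    a = _binary(graph)
    return shortest_path(csr_array(a), method="D", unweighted=True, directed=False)


def characteristic_path_length(distances: np.ndarray):
    """Mean over nodes of the mean distance to reachable other nodes.

    Returns ``(L, n_excluded)`` where ``n_excluded`` counts unreachable
    ordered pairs left out of the average; L is nan when no off-diagonal
    pair is reachable.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int((off & ~finite).sum())
    per_node = np.full(n, np.nan)
    for i in range(n):
        row = d[i, finite[i]]
        if row.size:
            per_node[i] = row.mean()
    if np.all(np.isnan(per_node)):
        return float("nan"), n_excluded
    return float(np.nanmean(per_node)), n_excluded


def global_efficiency(distances: np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs, with 1/inf = 0."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    pos = off & np.isfinite(d) & (d > 0)
    inv[pos] = 1.0 / d[pos]
    return float(inv[off].mean())


def local_efficiency(graph: ThresholdedGraph):
    """Per-node efficiency of the subgraph induced by each node's neighbours.

    E_loc,i = sum over ordered neighbour pairs of 1/d within the induced
    subgraph, divided by k_i (k_i - 1); 0 when k_i < 2.  Returns
    ``(per_node, mean)``.
    """
    a = _binary(graph)
    n = a.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        d = shortest_path(csr_array(sub), method="D", unweighted=True, directed=False)
        off = ~np.eye(nb.size, dtype=bool)
        inv = np.zeros_like(d)
        pos = off & np.isfinite(d) & (d > 0)
        inv[pos] = 1.0 / d[pos]
        e[i] = inv[off].sum() / (nb.size * (nb.size - 1))
    return e, float(e.mean())


def detect_modules(graph: ThresholdedGraph, seed: int = 0, n_restarts: int = 10):
    """Louvain community detection, best modularity over seeded restarts.

    Returns ``(partition, Q)`` with ``partition`` a length-M module-id
    array.  An edgeless graph yields singleton modules and Q = 0.
    """
    a = graph.adjacency
    n = a.shape[0]
    g = nx.from_numpy_array(a)
    if g.number_of_edges() == 0:
        return np.arange(n), 0.0
    best_part, best_q = None, -np.inf
    for r in range(n_restarts):
        communities = nx.community.louvain_communities(g, seed=seed + r, weight="weight")
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            best_part, best_q = communities, q
    partition = np.empty(n, dtype=int)
    for m, members in enumerate(best_part):
        partition[list(members)] = m
    return partition, float(best_q)


def participation_coefficient(graph: ThresholdedGraph, partition) -> np.ndarray:
    """P_i = 1 - sum_m (k_im / k_i)^2; 0 for isolated nodes."""
    a = graph.adjacency
    partition = np.asarray(partition, dtype=int)
    k = a.sum(axis=1)
    n_mod = partition.max() + 1
    # k_im: node-by-module degree
    kim = np.zeros((a.shape[0], n_mod))
    for m in range(n_mod):
        kim[:, m] = a[:, partition == m].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - ((kim / k[:, None]) ** 2).sum(axis=1)
    p[k == 0] = 0.0
    return p


def within_module_zscore(graph: ThresholdedGraph, partition) -> np.ndarray:
    """Within-module degree standardized by its module (population sd).

    z_i = (kappa_i - mean) / sd over node i's module; 0 when the module's
    sd is 0 (including singleton modules).
    """
    a = graph.adjacency
    partition = np.asarray(partition, dtype=int)
    z = np.zeros(a.shape[0])
    for m in np.unique(partition):
        members = np.flatnonzero(partition == m)
        kappa = a[np.ix_(members, members)].sum(axis=1)
        sd = kappa.std()  # population denominator
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z


def state_metrics(
    state_matrix: np.ndarray, tau: float = 0.3, seed: int = 0
):
    """Node and global indicator tables for one state matrix.

    Thresholds at ``tau``, computes all binary-graph indicators plus the
    weighted degree, and returns ``(node_table, global_table)`` as pandas
    objects ready to be written as delimited text.
    """
    gb = threshold_state(state_matrix, tau, "binary")
    gw = threshold_state(state_matrix, tau, "weighted")
    partition, q = detect_modules(gb, seed=seed)
    cc, mean_cc = clustering_coefficient(gb)
    d = shortest_path_lengths(gb)
    cpl, n_excluded = characteristic_path_length(d)
    eloc, mean_eloc = local_efficiency(gb)
    node_table = pd.DataFrame(
        {
            "node": np.arange(gb.n_nodes),
            "degree": degree(gb),
            "weighted_degree": degree(gw),
            "clustering": cc,
            "local_efficiency": eloc,
            "participation": participation_coefficient(gb, partition),
            "within_module_z": within_module_zscore(gb, partition),
            "module": partition,
        }
    )
    global_table = {
        "sparsity": gb.sparsity,
        "characteristic_path_length": cpl,
        "excluded_pairs": n_excluded,
        "global_efficiency": global_efficiency(d),
        "mean_clustering": mean_cc,
        "mean_local_efficiency": mean_eloc,
        "modularity": q,
        "n_modules": int(partition.max() + 1),
    }
    return node_table, global_table
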