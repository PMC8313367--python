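"""Edge-wise group-difference testing within connectivity states.

Each subject's edge value for a state is the element-wise mean of that
subject's windowed Fisher-Z matrices assigned to the state (subjects that
never visit the state are excluded and logged).  Group differences are
tested per edge with an independent two-sample t-test, and family-wise
error over edges is controlled either component-wise with the network-based
statistic (NBS) — connected components of edges with |t| above a primary
threshold, sized in edges, compared against the max-component null obtained
by permuting group labels — or edge-wise with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .cluster import StateAssignment
from .windows import WindowedFcSet

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTestResult",
    "NbsComponent",
    "NbsResult",
    "subject_state_fc",
    "collect_state_stacks",
    "edgewise_t",
    "nbs",
    "fdr_bh",
]


@dataclass
class EdgeTestResult:
    """Symmetric t and p matrices for one state and group pair."""

    t_matrix: np.ndarray
    p_matrix: np.ndarray
    df: int
    zero_variance: np.ndarray  # boolean mask of flagged degenerate edges


@dataclass
class NbsComponent:
    edges: list  # list of (i, j) node pairs
    size: int  # number of edges
    p_value: float


@dataclass
class NbsResult:
    primary_threshold: float
    components: list
    n_permutations: int
    seed: int
    t_matrix: np.ndarray
    null_max_sizes: np.ndarray

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.components), default=1.0)


def subject_state_fc(
    assignment: StateAssignment, windowed: WindowedFcSet, state: int
):
    """Mean M x M Fisher-Z matrix over a subject's windows in ``state``.

    Returns None (and logs the exclusion) when the subject has no window
    assigned to the state.
    """
    mask = np.asarray(assignment.labels) == state
    if not mask.any():
        logger.info(
            "subject %s has no windows in state %d; excluded",
            assignment.subject_id,
            state,
        )
        return None
    return windowed.matrices[mask].mean(axis=0)


def collect_state_stacks(
    assignments: list[StateAssignment],
    windowed_sets: list[WindowedFcSet],
    state: int,
    groups,
):
    """Stack per-subject state FC matrices for each requested group label."""
    stacks = {g: [] for g in groups}
    for a, w in zip(assignments, windowed_sets):
        if a.group not in stacks:
            continue
        fc = subject_state_fc(a, w, state)
        if fc is not None:
            stacks[a.group].append(fc)
    return {g: np.stack(v) if v else np.empty((0,)) for g, v in stacks.items()}


def _pooled_t(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled-variance two-sample t over the last axis=0 stacks."""
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    zero = denom == 0
    t = np.divide(diff, denom, out=np.zeros_like(diff), where=~zero)
    return t, df, zero


def edgewise_t(stack_a: np.ndarray, stack_b: np.ndarray) -> EdgeTestResult:
    """Independent two-sample t per edge; two-sided p.

    Stacks are (n, M, M) symmetric matrices.  Edges with zero pooled
    variance get t = 0, p = 1 and are flagged.
    """
    if stack_a.shape[0] < 2 or stack_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    m = stack_a.shape[1]
    iu = np.triu_indices(m, k=1)
    t_vec, df, zero = _pooled_t(stack_a[:, iu[0], iu[1]], stack_b[:, iu[0], iu[1]])
    p_vec = 2 * sps.t.sf(np.abs(t_vec), df)
    p_vec[zero] = 1.0

    def to_mat(v, fill=0.0):
        out = np.full((m, m), fill)
        out[iu] = v
        out[(iu[1], iu[0])] = v
        np.fill_diagonal(out, 0.0 if fill == 0.0 else 1.0)
        return out

    zmat = np.zeros((m, m), dtype=bool)
    zmat[iu] = zero
    zmat |= zmat.T
    return EdgeTestResult(
        t_matrix=to_mat(t_vec), p_matrix=to_mat(p_vec, fill=1.0), df=df,
        zero_variance=zmat,
    )


def _max_component_edges(supra_vec, iu, m):
    """Edge count of the largest connected component of suprathreshold edges."""
    idx = np.flatnonzero(supra_vec)
    if idx.size == 0:
        return 0
    rows, cols = iu[0][idx], iu[1][idx]
    adj = csr_array(
        (np.ones(idx.size), (rows, cols)), shape=(m, m)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[rows]
    return int(np.bincount(comp_of_edge).max())


def nbs(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    primary_threshold: float = 3.0,
    n_permutations: int = 5000,
    seed: int = 0,
) -> NbsResult:
    """Network-based statistic: component-level permutation test.

    Observed components are the connected components of the graph formed by
    edges with |t| >= ``primary_threshold``; component size is its edge
    count.  The null is the maximal component size under full relabelling
    of subjects across the two groups; each observed component gets
    p = (1 + #{perm max >= size}) / (P + 1).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    m = stack_a.shape[1]
    iu = np.triu_indices(m, k=1)
    a = stack_a[:, iu[0], iu[1]]
    b = stack_b[:, iu[0], iu[1]]
    na = a.shape[0]
    t_obs, _, _ = _pooled_t(a, b)
    supra = np.abs(t_obs) >= primary_threshold

    # observed components
    components = []
    idx = np.flatnonzero(supra)
    if idx.size:
        rows, cols = iu[0][idx], iu[1][idx]
        adj = csr_array((np.ones(idx.size), (rows, cols)), shape=(m, m))
        _, node_labels = connected_components(adj, directed=False)
        comp_of_edge = node_labels[rows]
        for c in np.unique(comp_of_edge):
            mask = comp_of_edge == c
            components.append(
                NbsComponent(
                    edges=[(int(i), int(j)) for i, j in zip(rows[mask], cols[mask])],
                    size=int(mask.sum()),
                    p_value=np.nan,
                )
            )

    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        t_perm, _, _ = _pooled_t(pooled[perm[:na]], pooled[perm[na:]])
        null_max[p] = _max_component_edges(
            np.abs(t_perm) >= primary_threshold, iu, m
        )
    for comp in components:
        comp.p_value = float(
            (1 + (null_max >= comp.size).sum()) / (n_permutations + 1)
        )

    t_mat = np.zeros((m, m))
    t_mat[iu] = t_obs
    t_mat += t_mat.T
    return NbsResult(
        primary_threshold=primary_threshold,
        components=components,
        n_permutations=n_permutations,
        seed=seed,
        t_matrix=t_mat,
        null_max_sizes=null_max,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
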