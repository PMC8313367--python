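"""Synthetic cohorts of ROI time series with planted connectivity states.

The generator emulates preprocessed resting-state ROI signals whose
covariance is piecewise stationary: a hidden Markov chain over K recurring
connectivity states selects, at each time point, a state-specific M x M
correlation matrix, and the observation is a zero-mean multivariate normal
draw from that matrix plus isotropic Gaussian noise.  Groups of subjects
differ through their switching models (dwell/transition behaviour) and,
optionally, through additive per-edge perturbations of selected state
covariances, so both dynamics-level and edge-level group differences can be
planted with known ground truth.

States are constructed with strictly descending mean off-diagonal
correlation ("mean FC") and a modular block pattern whose node-to-module
assignment is rotated from state to state, so states differ in pattern as
well as in level — the structure a k-means state analysis is meant to
recover.  There is no hemodynamic response, temporal autocorrelation within
a state, motion, or drift: given the state, samples are i.i.d., the simplest
model under which windowed Pearson correlation consistently estimates the
planted state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .windows import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "StateCovariance",
    "SwitchingModel",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "even_partition",
    "make_state_covariances",
    "sample_label_sequence",
    "sample_subject",
    "generate_cohort",
    "example_cohort_spec",
    "simulate_edge_groups",
]


@dataclass(frozen=True)
class StateCovariance:
    """One planted connectivity state: an SPD covariance with a target mean FC."""

    state_id: int
    cov: np.ndarray
    target_mean_fc: float

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "cov", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(c) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def correlation(self) -> np.ndarray:
        d = 1.0 / np.sqrt(np.diag(self.cov))
        return self.cov * np.outer(d, d)

    @property
    def mean_fc(self) -> float:
        """Mean off-diagonal entry of the correlation form."""
        r = self.correlation
        m = r.shape[0]
        return float((r.sum() - m) / (m * (m - 1)))


@dataclass(frozen=True)
class SwitchingModel:
    """First-order Markov chain over K states (row-stochastic transitions)."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        p = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", t)
        object.__setattr__(self, "initial_distribution", p)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or np.any(t > 1) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must be in [0, 1]")
        if np.any(np.abs(t.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(p.sum() - 1) > 1e-12 or p.shape[0] != t.shape[0]:
            raise ValueError("initial distribution must be length-K and sum to 1")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, switching model, optional edge deltas.

    ``fc_deltas`` maps state_id -> symmetric M x M additive perturbation of
    that state's covariance (zero diagonal), planting edge-level group
    differences for NBS-style tests.
    """

    label: str
    n_subjects: int
    switching: SwitchingModel
    fc_deltas: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each group needs at least one subject")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a multi-group synthetic cohort."""

    groups: tuple[GroupSpec, ...]
    n_regions: int
    n_timepoints: int
    tr_seconds: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0
    mean_fc_levels: tuple[float, ...] = (0.58, 0.39, 0.25, 0.20)
    n_blocks: int = 5
    contrast: float = 0.8

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        k = len(self.mean_fc_levels)
        for g in self.groups:
            if g.switching.n_states != k:
                raise ValueError("switching model order must match number of states")


@dataclass
class GroundTruth:
    """Planted parameters and per-subject time-point state labels (1..K)."""

    state_covariances: list[StateCovariance]
    group_models: dict[str, SwitchingModel]
    labels: dict[str, np.ndarray]
    group_of: dict[str, str]


def even_partition(M: int, n_blocks: int) -> list[list[int]]:
    """Split regions 0..M-1 into ``n_blocks`` contiguous, near-equal modules."""
    bounds = np.linspace(0, M, n_blocks + 1).astype(int)
    return [list(range(bounds[i], bounds[i + 1])) for i in range(n_blocks)]


def _max_contrast(level, f, contrast):
    """Largest usable within/between split keeping 0 <= b and w <= 0.95."""
    c_eff = contrast
    if f > 0:
        c_eff = min(c_eff, level / f)
    if f < 1:
        c_eff = min(c_eff, (0.95 - level) / (1 - f))
    return max(c_eff, 0.0)


def _contrast_for_z_gap(level, f, target_gap, cap):
    """Contrast whose Fisher-Z within/between gap equals ``target_gap``.

    Solved by bisection on c in [0, cap]; the gap arctanh(w) - arctanh(b)
    is strictly increasing in c.
    """
    def gap(c):
        return np.arctanh(level + c * (1 - f)) - np.arctanh(max(level - c * f, 0.0))

    if gap(cap) <= target_gap:
        return cap
    lo, hi = 0.0, cap
    for _ in range(60):
        mid = (lo + hi) / 2
        if gap(mid) < target_gap:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _block_correlation(M, level, assignment, c_eff):
    """Constant-block correlation with exact mean ``level`` off-diagonal."""
    if assignment is None or c_eff <= 0:
        c = np.full((M, M), level)
        np.fill_diagonal(c, 1.0)
        return c
    same = assignment[:, None] == assignment[None, :]
    f = _within_fraction(M, assignment)
    w = level + c_eff * (1 - f)
    b = level - c_eff * f
    c = np.where(same, w, b)
    np.fill_diagonal(c, 1.0)
    return c


def _within_fraction(M, assignment):
    same = assignment[:, None] == assignment[None, :]
    return (same.sum() - M) / 2 / (M * (M - 1) / 2)


def _spd_repair(c: np.ndarray, state_id: int) -> np.ndarray:
    eps = 1e-6
    for _ in range(60):
        if np.linalg.eigvalsh(c)[0] > 0:
            return c
        logger.warning("state %d: adding %.2g*I for SPD repair", state_id, eps)
        c = c + eps * np.eye(c.shape[0])
        d = 1.0 / np.sqrt(np.diag(c))
        c = c * np.outer(d, d)
        eps *= 2
    raise ValueError(
        f"state {state_id}: could not repair to SPD "
        f"(min eigenvalue {np.linalg.eigvalsh(c)[0]:.3g})"
    )


def make_state_covariances(
    M: int,
    K: int,
    mean_fc_levels,
    block_structure: list[list[int]] | None = None,
    seed: int = 0,
    contrast: float = 0.8,
) -> list[StateCovariance]:
    """Construct K SPD state correlation matrices with descending mean FC.

    Each state's mean off-diagonal correlation equals its entry of
    ``mean_fc_levels`` (strictly descending, in [0, 1)).  If
    ``block_structure`` (a module partition) is given, within-module
    correlations exceed between-module ones; the first state uses the
    partition as given and each later state applies a seeded permutation of
    the node-to-module assignment, so states are distinct connectivity
    patterns, not merely rescaled copies — the structure real recurring FC
    states exhibit.  The within/between split of every state is tuned so
    all states have the same Fisher-Z contrast (the largest gap the most
    constrained state can realize, capped by ``contrast``): states are then
    equally salient, and no state is systematically favoured when windows
    are ranked by FC-entry variance.  Deterministic given ``seed``.
    """
    levels = [float(x) for x in mean_fc_levels]
    if len(levels) != K:
        raise ValueError("need one mean FC level per state")
    if any(not (0 <= x < 1) for x in levels):
        raise ValueError("mean FC levels must lie in [0, 1)")
    if any(a <= b for a, b in zip(levels, levels[1:])):
        raise ValueError("mean FC levels must be strictly descending")
    if M < 2:
        raise ValueError("need at least 2 regions")

    base = None
    if block_structure is not None:
        base = np.empty(M, dtype=int)
        seen = []
        for b, members in enumerate(block_structure):
            base[list(members)] = b
            seen.extend(members)
        if sorted(seen) != list(range(M)):
            raise ValueError("block_structure must partition 0..M-1")

    out = []
    perm_rngs = np.random.SeedSequence(seed).spawn(K)
    assignments = []
    for k in range(K):
        if base is None:
            assignments.append(None)
        elif k == 0:
            assignments.append(base)
        else:
            assignments.append(base[np.random.default_rng(perm_rngs[k]).permutation(M)])

    contrasts = [0.0] * K
    if base is not None:
        f = _within_fraction(M, base)
        caps = [_max_contrast(level, f, contrast) for level in levels]
        target_gap = min(
            np.arctanh(lv + c * (1 - f)) - np.arctanh(max(lv - c * f, 0.0))
            for lv, c in zip(levels, caps)
        )
        contrasts = [
            _contrast_for_z_gap(lv, f, target_gap, c) for lv, c in zip(levels, caps)
        ]

    for k, level in enumerate(levels):
        c = _block_correlation(M, level, assignments[k], contrasts[k])
        c = _spd_repair(c, k + 1)
        out.append(StateCovariance(state_id=k + 1, cov=c, target_mean_fc=level))
    return out


def sample_label_sequence(model: SwitchingModel, L: int, seed) -> np.ndarray:
    """Length-L state label sequence (values 1..K) from the Markov chain."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum_t = np.cumsum(model.transition_matrix, axis=1)
    labels = np.empty(L, dtype=int)
    u = rng.random(L)
    labels[0] = np.searchsorted(np.cumsum(model.initial_distribution), u[0]) + 1
    for t in range(1, L):
        labels[t] = np.searchsorted(cum_t[labels[t - 1] - 1], u[t]) + 1
    return labels


def sample_subject(
    labels: np.ndarray,
    covs: list[StateCovariance],
    noise_sd: float,
    seed,
    *,
    subject_id: str = "synthetic",
    group: str = "",
    tr_seconds: float = 2.0,
    region_labels=None,
) -> RoiTimeSeries:
    """Draw one subject's series: row t ~ N(0, cov[labels[t]]) + noise.

    Deterministic given ``seed``; state rows are drawn in ascending state
    order so the draw order is independent of the label sequence's layout.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    by_id = {c.state_id: c for c in covs}
    missing = set(np.unique(labels)) - set(by_id)
    if missing:
        raise ValueError(f"labels refer to unknown states {sorted(missing)}")
    M = covs[0].cov.shape[0]
    if any(c.cov.shape[0] != M for c in covs):
        raise ValueError("state covariances disagree on number of regions")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.empty((labels.size, M))
    for sid in sorted(by_id):
        idx = np.flatnonzero(labels == sid)
        if idx.size == 0:
            continue
        chol = np.linalg.cholesky(by_id[sid].cov)
        X[idx] = rng.standard_normal((idx.size, M)) @ chol.T
    if noise_sd > 0:
        X += noise_sd * rng.standard_normal(X.shape)
    return RoiTimeSeries(
        subject_id=subject_id,
        group=group,
        data=X,
        tr_seconds=tr_seconds,
        region_labels=list(region_labels) if region_labels else [],
    )


def _apply_deltas(covs, deltas, group):
    if not deltas:
        return covs
    out = []
    for c in covs:
        if c.state_id in deltas:
            d = np.asarray(deltas[c.state_id], dtype=float)
            pert = _spd_repair(c.cov + d, c.state_id)
            logger.info("group %s: perturbed state %d edges", group, c.state_id)
            out.append(StateCovariance(c.state_id, pert, c.target_mean_fc))
        else:
            out.append(c)
    return out


def generate_cohort(spec: CohortSpec):
    """All subjects of a cohort plus the planted ground truth.

    Returns ``(subjects, truth)`` where ``subjects`` is a list of
    :class:`RoiTimeSeries` in deterministic (group, index) order and
    ``truth`` records every label sequence and planted parameter.  The same
    spec (including seed) always yields bit-identical output.
    """
    K = len(spec.mean_fc_levels)
    covs = make_state_covariances(
        spec.n_regions,
        K,
        spec.mean_fc_levels,
        even_partition(spec.n_regions, spec.n_blocks),
        seed=spec.seed,
        contrast=spec.contrast,
    )
    region_labels = [f"R{i + 1}" for i in range(spec.n_regions)]
    n_total = sum(g.n_subjects for g in spec.groups)
    children = np.random.SeedSequence(spec.seed).spawn(n_total)

    subjects: list[RoiTimeSeries] = []
    truth = GroundTruth(
        state_covariances=covs,
        group_models={g.label: g.switching for g in spec.groups},
        labels={},
        group_of={},
    )
    i = 0
    for g in spec.groups:
        group_covs = _apply_deltas(covs, g.fc_deltas, g.label)
        for j in range(g.n_subjects):
            lab_rng, obs_rng = (np.random.default_rng(s) for s in children[i].spawn(2))
            labels = sample_label_sequence(g.switching, spec.n_timepoints, lab_rng)
            sid = f"{g.label}-{j + 1:03d}"
            subjects.append(
                sample_subject(
                    labels,
                    group_covs,
                    spec.noise_sd,
                    obs_rng,
                    subject_id=sid,
                    group=g.label,
                    tr_seconds=spec.tr_seconds,
                    region_labels=region_labels,
                )
            )
            truth.labels[sid] = labels
            truth.group_of[sid] = g.label
            i += 1
    return subjects, truth


def _sticky_model(stationary, self_stay) -> SwitchingModel:
    """Sticky chain T = s*I + (1-s)*1 pi^T with stationary distribution pi."""
    pi = np.asarray(stationary, dtype=float)
    pi = pi / pi.sum()
    t = self_stay * np.eye(pi.size) + (1 - self_stay) * np.tile(pi, (pi.size, 1))
    return SwitchingModel(transition_matrix=t, initial_distribution=pi)


def example_cohort_spec(
    n_per_group=(30, 30, 30),
    n_regions: int = 30,
    n_timepoints: int = 150,
    seed: int = 0,
    noise_sd: float = 0.2,
    group_labels=("NC", "eMCI", "lMCI"),
    self_stay=(0.995, 0.9925, 0.990),
    stationary=(0.16, 0.35, 0.38, 0.11),
    mean_fc_levels=(0.58, 0.39, 0.25, 0.20),
    tr_seconds: float = 2.0,
) -> CohortSpec:
    """Default three-group study cohort with four planted states.

    State occupancy is planted to favour the two middle states (combined
    stationary mass 0.73) and the control-like group is given the stickiest
    chain (fewest transitions), the qualitative pattern reported for real
    MCI cohorts.  Mean FC levels descend 0.58/0.39/0.25/0.20.
    """
    groups = tuple(
        GroupSpec(label=lab, n_subjects=n, switching=_sticky_model(stationary, s))
        for lab, n, s in zip(group_labels, n_per_group, self_stay)
    )
    return CohortSpec(
        groups=groups,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        tr_seconds=tr_seconds,
        noise_sd=noise_sd,
        seed=seed,
        mean_fc_levels=tuple(mean_fc_levels),
    )


def simulate_edge_groups(
    n_a: int,
    n_b: int,
    n_nodes: int,
    effect_edges=None,
    effect_size: float = 0.0,
    seed: int = 0,
):
    """Two groups of per-subject symmetric edge matrices for test calibration.

    Edges are independent unit-variance Gaussians; group B is shifted by
    ``effect_size`` standard deviations on ``effect_edges`` (a list of (i, j)
    node pairs).  Returns ``(stack_a, stack_b)`` of shape (n, M, M) with zero
    diagonals — the input expected by the edge-wise and NBS tests.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    e = iu[0].size

    def build(n, shift):
        vecs = rng.standard_normal((n, e)) + shift
        out = np.zeros((n, n_nodes, n_nodes))
        out[:, iu[0], iu[1]] = vecs
        out += out.transpose(0, 2, 1)
        return out

    shift = np.zeros(e)
    if effect_edges is not None and effect_size:
        pos = {tuple(sorted(p)): k for k, p in enumerate(zip(iu[0], iu[1]))}
        for i, j in effect_edges:
            shift[pos[tuple(sorted((i, j)))]] = effect_size
    return build(n_a, 0.0), build(n_b, shift)
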