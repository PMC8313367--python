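"""Connectivity-state extraction by two-stage k-means with Manhattan distance.

The feature for clustering is the vectorized upper triangle of each windowed
Fisher-Z matrix (length M(M-1)/2).  Stage 1 clusters a resampled subset of
windows — for every subject, the ``n_exemplars`` windows whose FC-entry
variance is largest — with many k-means++ restarts; stage 2 then runs a
single k-means to convergence on *all* windows of all subjects, initialized
at the stage-1 centroids.  States are finally ordered by descending centroid
mean and window assignments relabelled accordingly.

Distances default to L1 (Manhattan): in the high-dimensional FC feature
space L1 is the customary similarity measure for this pipeline family.
Under an L1 objective the cost-minimizing centroid is the coordinate-wise
median, so the default update is the median, which guarantees the recorded
inertia is non-increasing across iterations; a coordinate-wise mean update
(the squared-error convention) is available via ``update="mean"`` but loses
that guarantee.  The cluster number is either fixed (the analysis default is
k = 4) or chosen by the elbow rule on the intra/inter cluster distance
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .windows import WindowedFcSet, devectorize_upper, window_variance

__all__ = [
    "KmeansResult",
    "ElbowCurve",
    "StateSet",
    "StateAssignment",
    "BootstrapResult",
    "manhattan_distance",
    "kmeans_pp_init",
    "kmeans",
    "variance_ranking",
    "select_exemplars",
    "elbow_select_k",
    "two_stage_cluster",
    "match_states",
    "bootstrap_validate",
]

_METRICS = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclass
class KmeansResult:
    """One converged k-means solution (labels are 1-based)."""

    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    n_iter: int
    seed: int
    inertia_trace: list
    reseed_iterations: list


@dataclass
class ElbowCurve:
    """Intra/inter distance ratio per candidate k and the chosen bend."""

    k_values: np.ndarray
    ratio: np.ndarray
    chosen_k: int


@dataclass
class StateSet:
    """K state matrices ordered by descending centroid mean."""

    states: np.ndarray  # (K, M, M)
    state_means: np.ndarray  # mean of centroid entries, descending
    occupancy: np.ndarray  # fraction of all windows per state, sums to 1
    centroid_vectors: np.ndarray  # (K, M(M-1)/2)

    @property
    def k(self) -> int:
        return self.states.shape[0]


@dataclass
class StateAssignment:
    """Per-subject window-state label sequence (1..K)."""

    subject_id: str
    group: str
    labels: np.ndarray


@dataclass
class BootstrapResult:
    reference: StateSet
    replicates: list
    table: pd.DataFrame


def manhattan_distance(a, b) -> float:
    """Sum of absolute coordinate differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.abs(a - b).sum())


def _cost_matrix(samples, centroids, metric):
    """Per-sample per-centroid cost: L1 distance, or squared L2 (Eq.-2 style)."""
    d = cdist(samples, centroids, _METRICS[metric])
    return d * d if metric == "euclidean" else d


def kmeans_pp_init(samples, k, seed, metric: str = "manhattan") -> np.ndarray:
    """k-means++ seeding: next center with probability prop. to squared cost."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    d2 = cdist(samples, samples[chosen], _METRICS[metric]).ravel() ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a chosen center
            remaining = np.setdiff1d(np.arange(n), chosen)
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
        nd = cdist(samples, samples[[chosen[-1]]], _METRICS[metric]).ravel() ** 2
        d2 = np.minimum(d2, nd)
    return samples[chosen].copy()


def _update_centroids(samples, labels0, k, update):
    agg = np.median if update == "median" else np.mean
    cents = np.empty((k, samples.shape[1]))
    empty = []
    for c in range(k):
        members = samples[labels0 == c]
        if members.shape[0] == 0:
            empty.append(c)
        else:
            cents[c] = agg(members, axis=0)
    return cents, empty


def kmeans(
    samples,
    k: int,
    init_centroids=None,
    metric: str = "manhattan",
    max_iter: int = 300,
    n_restarts: int = 1,
    seed: int = 0,
    update: str | None = None,
) -> KmeansResult:
    """Lloyd iterations under the configured metric, best of ``n_restarts``.

    Assignment goes to the nearest centroid (ties to the lowest index);
    the update is the coordinate-wise median for the manhattan metric and
    the mean for euclidean unless ``update`` overrides it.  Inertia (sum of
    per-sample costs) is recorded after every assignment step.  A cluster
    emptied by an update is re-seeded at the sample farthest from its
    assigned centroid and the iteration logged.  When ``init_centroids`` is
    given a single run from those centers is performed.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("fewer samples than clusters")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if update is None:
        update = "median" if metric == "manhattan" else "mean"
    if update not in ("median", "mean"):
        raise ValueError(f"unknown update rule {update!r}")

    if init_centroids is not None:
        n_restarts = 1
    restart_seeds = np.random.SeedSequence(seed).spawn(n_restarts)

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(restart_seeds[r])
        if init_centroids is not None:
            cents = np.array(init_centroids, dtype=float)
            if cents.shape != (k, samples.shape[1]):
                raise ValueError("init_centroids has wrong shape")
        else:
            cents = kmeans_pp_init(samples, k, rng, metric)
        prev = None
        trace: list = []
        reseeds: list = []
        labels0 = np.zeros(n, dtype=int)
        for it in range(max_iter):
            cost = _cost_matrix(samples, cents, metric)
            labels0 = cost.argmin(axis=1)  # argmin takes lowest index on ties
            trace.append(float(cost[np.arange(n), labels0].sum()))
            if prev is not None and np.array_equal(labels0, prev):
                break
            prev = labels0.copy()
            cents, empty = _update_centroids(samples, labels0, k, update)
            if empty:
                per_sample = cost[np.arange(n), labels0]
                for c in empty:
                    far = int(np.argmax(per_sample))
                    cents[c] = samples[far]
                    per_sample[far] = -np.inf
                reseeds.append(it)
        result = KmeansResult(
            centroids=cents,
            labels=labels0 + 1,
            inertia=trace[-1],
            n_iter=len(trace),
            seed=seed,
            inertia_trace=trace,
            reseed_iterations=reseeds,
        )
        if best is None or result.inertia < best.inertia:
            best = result
    return best


def variance_ranking(subject: WindowedFcSet) -> np.ndarray:
    """Window indices ordered by descending FC-entry variance, ties earliest-first."""
    variances = np.var(subject.vectors(), axis=1)
    return np.argsort(-variances, kind="stable")


def select_exemplars(subject: WindowedFcSet, n_exemplars: int) -> np.ndarray:
    """The ``n_exemplars`` highest-variance window vectors of one subject."""
    n = subject.n_windows
    if not 1 <= n_exemplars <= n:
        raise ValueError(f"n_exemplars must be in 1..{n}")
    idx = variance_ranking(subject)[:n_exemplars]
    return subject.vectors()[idx]


def elbow_select_k(
    samples,
    k_range=range(2, 11),
    metric: str = "manhattan",
    seed: int = 0,
    n_restarts: int = 20,
    update: str | None = None,
) -> ElbowCurve:
    """Elbow rule on the intra/inter cluster distance ratio.

    ratio(k) = mean distance of samples to their own centroid divided by the
    mean pairwise distance between centroids.  The ratio falls while added
    clusters absorb genuinely separated structure and turns back up once a
    true cluster is split (the split halves pull two centroids close
    together, shrinking the denominator), so the chosen k is the first
    local minimum of the curve — the smallest k beyond which adding a
    cluster stops improving the ratio.  The curve is returned so a caller
    can override manually.
    """
    samples = np.asarray(samples, dtype=float)
    ks = np.asarray(list(k_range), dtype=int)
    if ks.size < 2 or ks.max() >= samples.shape[0]:
        raise ValueError("k_range must hold >= 2 values below the sample count")
    if np.all(samples == samples[0]):
        raise ValueError("all samples identical; elbow undefined")
    if update is None:
        update = "median" if metric == "manhattan" else "mean"

    seeds = np.random.SeedSequence(seed).spawn(ks.size)
    dist_name = _METRICS[metric]
    ratios = np.empty(ks.size)
    for i, k in enumerate(ks):
        res = kmeans(
            samples,
            int(k),
            metric=metric,
            n_restarts=n_restarts,
            seed=seeds[i].generate_state(1)[0] % (2**31),
            update=update,
        )
        within = cdist(samples, res.centroids, dist_name)[
            np.arange(samples.shape[0]), res.labels - 1
        ].mean()
        pair = cdist(res.centroids, res.centroids, dist_name)
        between = pair[np.triu_indices(int(k), k=1)].mean()
        ratios[i] = within / between

    chosen = int(ks[-1])
    for i in range(ks.size):
        left = ratios[i - 1] if i > 0 else np.inf
        right = ratios[i + 1] if i < ks.size - 1 else np.inf
        if ratios[i] <= left and ratios[i] <= right:
            chosen = int(ks[i])
            break
    return ElbowCurve(k_values=ks, ratio=ratios, chosen_k=chosen)


def _order_states(centroids, labels):
    """Permutation ordering states by descending mean, ties by first use."""
    means = centroids.mean(axis=1)
    first = np.full(centroids.shape[0], np.iinfo(np.int64).max)
    lab0, pos = np.unique(labels, return_index=True)
    first[lab0 - 1] = pos
    return np.lexsort((first, -means))


def two_stage_cluster(
    cohort: list[WindowedFcSet],
    k: int,
    n_exemplars: int = 7,
    metric: str = "manhattan",
    seed: int = 0,
    stage1_restarts: int = 50,
    update: str | None = None,
    max_iter: int = 300,
):
    """Exemplar-then-full two-stage clustering of a cohort's windows.

    Returns ``(state_set, assignments)``: K states ordered by descending
    centroid mean, and one 1-based label sequence per subject.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    s1_seed, s2_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    exemplars = np.vstack(
        [select_exemplars(w, min(n_exemplars, w.n_windows)) for w in cohort]
    )
    stage1 = kmeans(
        exemplars,
        k,
        metric=metric,
        n_restarts=stage1_restarts,
        seed=s1_seed,
        update=update,
        max_iter=max_iter,
    )
    all_vectors = np.vstack([w.vectors() for w in cohort])
    counts = [w.n_windows for w in cohort]
    stage2 = kmeans(
        all_vectors,
        k,
        init_centroids=stage1.centroids,
        metric=metric,
        seed=s2_seed,
        update=update,
        max_iter=max_iter,
    )

    order = _order_states(stage2.centroids, stage2.labels)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    centroids = stage2.centroids[order]
    labels = relabel[stage2.labels - 1]

    occupancy = np.bincount(labels, minlength=k + 1)[1:] / labels.size
    states = np.stack([devectorize_upper(c) for c in centroids])
    state_set = StateSet(
        states=states,
        state_means=centroids.mean(axis=1),
        occupancy=occupancy,
        centroid_vectors=centroids,
    )
    assignments = []
    start = 0
    for w, n in zip(cohort, counts):
        assignments.append(
            StateAssignment(
                subject_id=w.subject_id, group=w.group, labels=labels[start : start + n]
            )
        )
        start += n
    return state_set, assignments


def match_states(reference: np.ndarray, other: np.ndarray):
    """Hungarian matching of centroid vectors by maximal Pearson correlation.

    Returns ``(mapping, correlations)`` where ``mapping[i]`` is the row of
    ``other`` paired with reference state i.
    """
    k = reference.shape[0]
    corr = np.corrcoef(reference, other)[:k, k:]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


def bootstrap_validate(
    cohort: list[WindowedFcSet],
    k: int,
    B: int,
    seed: int = 0,
    n_exemplars: int = 7,
    metric: str = "manhattan",
    stage1_restarts: int = 50,
    update: str | None = None,
    indices_override=None,
) -> BootstrapResult:
    """Stability of the extracted states under subject-level resampling.

    Each of B replicates resamples subjects with replacement (same cohort
    size), reruns the two-stage clustering, and orders states by mean.  The
    similarity table reports, per replicate and per state, the Pearson
    correlation of the matched replicate centroid with the full-cohort
    centroid and the replicate's state occupancy.  ``indices_override`` (a
    list of index arrays) substitutes for the random resample in tests.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = np.random.SeedSequence(seed).spawn(B + 1)
    ref_seed = int(ss[0].generate_state(1)[0] % (2**31))
    reference, _ = two_stage_cluster(
        cohort, k, n_exemplars, metric, ref_seed, stage1_restarts, update
    )
    rows = []
    replicates = []
    n = len(cohort)
    for b in range(B):
        rng = np.random.default_rng(ss[b + 1])
        rep_seed = int(rng.integers(2**31))
        idx = (
            np.asarray(indices_override[b])
            if indices_override is not None
            else rng.integers(0, n, size=n)
        )
        rep, _ = two_stage_cluster(
            [cohort[i] for i in idx], k, n_exemplars, metric, rep_seed,
            stage1_restarts, update,
        )
        mapping, corrs = match_states(
            reference.centroid_vectors, rep.centroid_vectors
        )
        replicates.append(rep)
        for s in range(k):
            rows.append(
                {
                    "replicate": b,
                    "state": s + 1,
                    "centroid_correlation": corrs[s],
                    "occupancy": rep.occupancy[mapping[s]],
                }
            )
    return BootstrapResult(
        reference=reference, replicates=replicates, table=pd.DataFrame(rows)
    )
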