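"""Temporal statistics of window-state label sequences.

For each subject the state label sequence over windows yields: occupancy
(fraction of windows per state), mean dwelling time (mean length, in
windows, of maximal runs of a state), visit counts, and the number of
transitions (adjacent unequal labels).  Group differences in these scalars
are tested with a two-sample t-test (pooled variance by default, Welch
optionally).  Dwell time is reported in windows; multiply by
step_tr * tr_seconds for seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import StateAssignment

__all__ = [
    "SubjectDynamics",
    "run_lengths",
    "mean_dwell_time",
    "n_transitions",
    "state_fractions",
    "subject_dynamics",
    "dynamics_table",
    "group_compare",
]


@dataclass
class SubjectDynamics:
    """Per-subject temporal summary; arrays are indexed by state-1."""

    subject_id: str
    group: str
    fractions: np.ndarray
    mean_dwell: np.ndarray
    n_visits: np.ndarray
    transitions: int


def run_lengths(labels: np.ndarray):
    """(state, length) pairs of the maximal runs of a label sequence."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def mean_dwell_time(labels, state: int) -> float:
    """Mean length (windows) of maximal runs of ``state``; 0 if never visited."""
    states, lengths = run_lengths(labels)
    mine = lengths[states == state]
    return float(mine.mean()) if mine.size else 0.0


def n_transitions(labels) -> int:
    """Number of adjacent unequal label pairs."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    return int((np.diff(labels) != 0).sum())


def state_fractions(labels, K: int) -> np.ndarray:
    """Occupancy: fraction of windows spent in each state 1..K."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > K:
        raise ValueError("labels out of range 1..K")
    return np.bincount(labels, minlength=K + 1)[1:] / labels.size


def subject_dynamics(assignment: StateAssignment, K: int) -> SubjectDynamics:
    states, lengths = run_lengths(assignment.labels)
    dwell = np.zeros(K)
    visits = np.zeros(K, dtype=int)
    for s in range(1, K + 1):
        mine = lengths[states == s]
        visits[s - 1] = mine.size
        if mine.size:
            dwell[s - 1] = mine.mean()
    return SubjectDynamics(
        subject_id=assignment.subject_id,
        group=assignment.group,
        fractions=state_fractions(assignment.labels, K),
        mean_dwell=dwell,
        n_visits=visits,
        transitions=n_transitions(assignment.labels),
    )


def dynamics_table(assignments: list[StateAssignment], K: int) -> pd.DataFrame:
    """Long-format per-subject dynamics (one row per subject and state)."""
    rows = []
    for a in assignments:
        d = subject_dynamics(a, K)
        for s in range(K):
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "group": d.group,
                    "state": s + 1,
                    "fraction": d.fractions[s],
                    "mean_dwell": d.mean_dwell[s],
                    "n_visits": d.n_visits[s],
                    "transitions": d.transitions,
                }
            )
    return pd.DataFrame(rows)


def group_compare(values_a, values_b, welch: bool = False):
    """Two-sample t-test on a per-subject scalar; returns (t, two-sided p).

    Pooled-variance Student test by default, Welch when ``welch``.  If both
    groups have zero variance and equal means the result is (0.0, 1.0) by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
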