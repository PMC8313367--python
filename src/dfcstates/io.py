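"""Delimited-text readers and writers for the pipeline's artifacts.

Formats are deliberately plain: per-subject time series as tab-delimited
L x M matrices with a region-label header, a two-column cohort manifest
(subject_id, group), ground truth as JSON, state sets as one TSV matrix per
state plus a JSON sidecar, and window-state assignments as a long table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import StateAssignment, StateSet
from .synth import GroundTruth
from .windows import RoiTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "write_state_set",
    "read_state_set",
    "write_assignments",
    "read_assignments",
]


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False
    )


def read_timeseries(
    path, subject_id: str | None = None, group: str = "", tr_seconds: float = 2.0
) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id or Path(path).stem,
        group=group,
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_labels=list(df.columns),
    )


def write_cohort(out_dir, subjects, truth: GroundTruth | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        write_timeseries(ts, out / f"{ts.subject_id}.tsv")
        rows.append({"subject_id": ts.subject_id, "group": ts.group})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    if truth is not None:
        write_ground_truth(truth, out / "ground_truth.json")


def read_cohort(in_dir, tr_seconds: float = 2.0) -> list[RoiTimeSeries]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    return [
        read_timeseries(
            in_dir / f"{row.subject_id}.tsv",
            subject_id=row.subject_id,
            group=row.group,
            tr_seconds=tr_seconds,
        )
        for row in manifest.itertuples()
    ]


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "states": [
            {
                "state_id": c.state_id,
                "target_mean_fc": c.target_mean_fc,
                "covariance": c.cov.tolist(),
            }
            for c in truth.state_covariances
        ],
        "group_models": {
            g: {
                "transition_matrix": m.transition_matrix.tolist(),
                "initial_distribution": m.initial_distribution.tolist(),
            }
            for g, m in truth.group_models.items()
        },
        "labels": {s: lab.tolist() for s, lab in truth.labels.items()},
        "group_of": truth.group_of,
    }
    Path(path).write_text(json.dumps(payload))


def write_state_set(states: StateSet, out_dir, extra_meta: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, mat in enumerate(states.states):
        np.savetxt(out / f"state_{i + 1}.tsv", mat, delimiter="\t")
    meta = {
        "k": states.k,
        "state_means": states.state_means.tolist(),
        "occupancy": states.occupancy.tolist(),
    }
    meta.update(extra_meta or {})
    (out / "states.json").write_text(json.dumps(meta, default=str))


def read_state_set(in_dir) -> StateSet:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "states.json").read_text())
    mats = np.stack(
        [
            np.loadtxt(in_dir / f"state_{i + 1}.tsv", delimiter="\t")
            for i in range(meta["k"])
        ]
    )
    iu = np.triu_indices(mats.shape[1], k=1)
    return StateSet(
        states=mats,
        state_means=np.asarray(meta["state_means"]),
        occupancy=np.asarray(meta["occupancy"]),
        centroid_vectors=mats[:, iu[0], iu[1]],
    )


def write_assignments(assignments: list[StateAssignment], path) -> None:
    rows = [
        {
            "subject_id": a.subject_id,
            "group": a.group,
            "window_index": w,
            "state": int(s),
        }
        for a in assignments
        for w, s in enumerate(a.labels)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> list[StateAssignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("window_index")
        out.append(
            StateAssignment(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                labels=sub["state"].to_numpy(dtype=int),
            )
        )
    return out
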