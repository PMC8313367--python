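"""End-to-end orchestration: simulate -> windows -> cluster -> dynamics ->
graph -> edge statistics, with a machine-readable JSON report.

All randomness flows from one master seed, split per stage with
``numpy.random.SeedSequence``; the configuration (and its hash) is embedded
in the report so a bundle is fully reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import dynamics as dyn
from . import graph as gr
from . import stats as st
from .cluster import elbow_select_k, select_exemplars, two_stage_cluster
from .synth import example_cohort_spec, generate_cohort
from .windows import build_windowed_fc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "sweep_window_lengths"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis.

    Defaults follow the analysis conventions: 30 s rectangular window
    (sweepable over 30/40/50/60 s), 1-TR step, k = 4 states (or "auto" for
    the elbow rule), 7 exemplar windows per subject, Manhattan metric,
    connection threshold tau = 0.3, NBS primary threshold |t| >= 3 with
    5000 permutations.
    """

    window_seconds: float = 30.0
    step_tr: int = 1
    k: int | str = 4
    exemplars: int = 7
    metric: str = "manhattan"
    tau: float = 0.3
    primary_threshold: float = 3.0
    permutations: int = 5000
    seed: int = 0
    stage1_restarts: int = 50
    elbow_restarts: int = 20
    k_range: tuple = (2, 10)
    nbs_states: tuple = ()  # empty -> two highest-occupancy states
    simulate: dict = field(default_factory=dict)  # kwargs for example_cohort_spec

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage_seeds(master: int, n: int):
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master).spawn(n)
    ]


def run_pipeline(config: PipelineConfig, cohort=None, truth=None) -> dict:
    """Execute every stage on ``cohort`` (simulated when omitted).

    Returns the report dictionary; callers can serialize it with
    ``json.dumps(report, default=float)``.
    """
    sim_seed, cluster_seed, graph_seed, nbs_seed = _stage_seeds(config.seed, 4)
    if cohort is None:
        spec = example_cohort_spec(seed=sim_seed, **config.simulate)
        cohort, truth = generate_cohort(spec)
        logger.info("simulated %d subjects", len(cohort))

    windowed = [
        build_windowed_fc(
            ts, step=config.step_tr, window_seconds=config.window_seconds
        )
        for ts in cohort
    ]

    if config.k == "auto":
        pool = np.vstack(
            [select_exemplars(w, min(config.exemplars, w.n_windows)) for w in windowed]
        )
        curve = elbow_select_k(
            pool,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            metric=config.metric,
            seed=cluster_seed,
            n_restarts=config.elbow_restarts,
        )
        k = curve.chosen_k
        elbow = {"k_values": curve.k_values.tolist(), "ratio": curve.ratio.tolist()}
    else:
        k = int(config.k)
        elbow = None

    states, assignments = two_stage_cluster(
        windowed,
        k,
        n_exemplars=config.exemplars,
        metric=config.metric,
        seed=cluster_seed,
        stage1_restarts=config.stage1_restarts,
    )

    table = dyn.dynamics_table(assignments, k)
    groups = sorted({a.group for a in assignments})
    per_subject = table.drop_duplicates("subject_id")
    dynamics_tests = []
    for ga, gb in itertools.combinations(groups, 2):
        va = per_subject.loc[per_subject.group == ga, "transitions"]
        vb = per_subject.loc[per_subject.group == gb, "transitions"]
        if len(va) >= 2 and len(vb) >= 2:
            t, p = dyn.group_compare(va, vb)
            dynamics_tests.append(
                {"metric": "transitions", "groups": [ga, gb], "t": t, "p": p}
            )

    graph_report = []
    for s in range(k):
        _, glob = gr.state_metrics(states.states[s], tau=config.tau, seed=graph_seed)
        glob["state"] = s + 1
        graph_report.append(glob)

    nbs_states = list(config.nbs_states) or (
        (np.argsort(-states.occupancy)[:2] + 1).tolist() if k >= 2 else [1]
    )
    nbs_report = []
    if len(groups) >= 2:
        for s in nbs_states:
            stacks = st.collect_state_stacks(assignments, windowed, int(s), groups)
            for ga, gb in itertools.combinations(groups, 2):
                if stacks[ga].shape[0] < 2 or stacks[gb].shape[0] < 2:
                    continue
                res = st.nbs(
                    stacks[ga],
                    stacks[gb],
                    primary_threshold=config.primary_threshold,
                    n_permutations=config.permutations,
                    seed=nbs_seed,
                )
                nbs_report.append(
                    {
                        "state": int(s),
                        "groups": [ga, gb],
                        "components": [
                            {"size": c.size, "p": c.p_value, "edges": c.edges}
                            for c in res.components
                        ],
                    }
                )

    report = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_subjects": len(cohort),
        "window_length_tr": windowed[0].window_length_tr,
        "n_windows_per_subject": windowed[0].n_windows,
        "k": k,
        "elbow": elbow,
        "state_means": states.state_means.tolist(),
        "occupancy": states.occupancy.tolist(),
        "dynamics_tests": dynamics_tests,
        "graph": graph_report,
        "nbs": nbs_report,
    }
    return report


def sweep_window_lengths(config: PipelineConfig, seconds=(30, 40, 50, 60), cohort=None):
    """Re-run the pipeline for several window lengths on one cohort."""
    if cohort is None:
        sim_seed = _stage_seeds(config.seed, 4)[0]
        spec = example_cohort_spec(seed=sim_seed, **config.simulate)
        cohort, _ = generate_cohort(spec)
    reports = {}
    for s in seconds:
        cfg = PipelineConfig(**{**asdict(config), "window_seconds": float(s)})
        reports[s] = run_pipeline(cfg, cohort=cohort)
    return reports
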