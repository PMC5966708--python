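"""Rule-based cognitive-risk classification.

Per task, the two-cluster solution is *tagged*: the cluster whose centre
matches the task's hazardous cognitive state gets the cognitive tag 0
(risky) and the other gets 1 (risk-free).  For cognitively loading tasks
the higher pupil-dilation centre is risky; for monotony-dominated tasks
the lower one is.  Pupil dilation is the primary indicator; exact pupil
ties fall back to the GSR centre compared in the task's expected
direction, then to blink rate, and a full three-way tie is an error
rather than a guess.

A task is **low risk** for a participant only when both conditions hold:
risk-free cognitive state (tag 1) *and* task performance of at least 70%.
Any other combination is high risk.  The participant's **general risk
class** is low when at least half of the battery — 3 or more of the 6
tasks — is low risk.

Task performance is additionally bucketed for description: below 70% is
*bad*, 70-90% (inclusive) *good*, and above 90% *excellent*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .cluster import ClusterSolution
from .tasks import DEFAULT_TASKS, RiskyDirection, TaskSpec

__all__ = [
    "TaggingError",
    "RiskProfiles",
    "tag_clusters",
    "performance_class",
    "task_risk",
    "general_risk",
    "build_risk_profiles",
    "PERFORMANCE_THRESHOLD",
]

#: minimum task performance (%) admitting the low-risk class
PERFORMANCE_THRESHOLD = 70.0

RISKY_TAG, SAFE_TAG = 0, 1


class TaggingError(RuntimeError):
    """Cluster tagging could not be decided from the centres."""


def tag_clusters(solution: ClusterSolution, spec: TaskSpec) -> Dict[int, int]:
    """Map each cluster index of a 2-cluster solution to a cognitive tag.

    Tag 0 marks the risky cognitive state, tag 1 the risk-free state.
    The decision uses the pupil-dilation centre (feature column 0) in the
    direction given by the task's hazardous state; exact ties fall back
    to GSR (column 2) then blink rate (column 1), each compared in the
    task's expected risky direction.
    """
    if solution.k != 2:
        raise TaggingError(f"tagging requires k=2, got k={solution.k}")
    centers = np.asarray(solution.centers, dtype=float)

    pupil_sign = 1 if spec.risky_direction == RiskyDirection.LOADING else -1
    # tie-break order: pupil, GSR, blink — with per-task expected signs
    for col, sign in ((0, pupil_sign),
                      (2, spec.expected_risky_sign[2]),
                      (1, spec.expected_risky_sign[1])):
        diff = centers[0, col] - centers[1, col]
        if diff != 0:
            risky_idx = 0 if diff * sign > 0 else 1
            return {risky_idx: RISKY_TAG, 1 - risky_idx: SAFE_TAG}
    raise TaggingError(
        f"{spec.task_id}: cluster centres tie on all three features; "
        "cannot tag without guessing")


def performance_class(performance_pct: float) -> str:
    """Bucket a task performance: <70 bad, 70-90 good, >90 excellent."""
    if not 0 <= performance_pct <= 100:
        raise ValueError(f"performance {performance_pct} outside [0, 100]")
    if performance_pct < PERFORMANCE_THRESHOLD:
        return "bad"
    if performance_pct <= 90:
        return "good"
    return "excellent"


def task_risk(cognitive_tag: int, performance_pct: float,
              threshold: float = PERFORMANCE_THRESHOLD) -> str:
    """Low risk iff the cognitive state is risk-free (tag 1) and the
    performance reaches the threshold; every other combination is high."""
    if cognitive_tag not in (RISKY_TAG, SAFE_TAG):
        raise ValueError(f"cognitive tag must be 0 or 1, got {cognitive_tag}")
    return "low" if (cognitive_tag == SAFE_TAG
                     and performance_pct >= threshold) else "high"


def general_risk(task_risks: Sequence[str], low_threshold: int = 3,
                 n_tasks: int = 6) -> str:
    """Participant-level class: low iff at least ``low_threshold`` of the
    ``n_tasks`` task risks are low (the 50% cut-off for 3 of 6)."""
    risks = list(task_risks)
    if len(risks) != n_tasks:
        raise ValueError(f"expected {n_tasks} task risks, got {len(risks)}")
    bad = set(risks) - {"low", "high"}
    if bad:
        raise ValueError(f"invalid task risk values {bad}")
    return "low" if risks.count("low") >= low_threshold else "high"


@dataclass
class RiskProfiles:
    """Cohort risk classification output.

    ``per_task`` has one row per participant x task with the cognitive
    tag, performance class and task risk; ``general`` one row per
    participant with the low-task count and general risk class.
    """

    per_task: pd.DataFrame
    general: pd.DataFrame

    def summary(self) -> Dict:
        counts = (self.general["general_risk"].value_counts()
                  .reindex(["high", "low"], fill_value=0))
        per_task = {
            tid: grp["task_risk"].value_counts()
                 .reindex(["high", "low"], fill_value=0).to_dict()
            for tid, grp in self.per_task.groupby("task", sort=False)
        }
        return {"general": counts.to_dict(), "per_task": per_task}


def build_risk_profiles(
    feature_table: pd.DataFrame,
    solutions: Mapping[str, ClusterSolution],
    tasks: Sequence[TaskSpec] = DEFAULT_TASKS,
    low_threshold: int = 3,
) -> RiskProfiles:
    """Apply tagging, per-task risk and general risk to a clustered cohort.

    ``feature_table`` must contain ``participant, task, performance_pct``;
    ``solutions`` maps each task id to its 2-cluster solution whose
    assignment order matches the table's participants sorted by id.
    """
    spec_by_id = {t.task_id: t for t in tasks}
    rows = []
    for tid, spec in spec_by_id.items():
        if tid not in solutions:
            raise ValueError(f"missing cluster solution for task {tid}")
        sol = solutions[tid]
        tags = tag_clusters(sol, spec)
        grp = (feature_table[feature_table["task"] == tid]
               .sort_values("participant").reset_index(drop=True))
        if len(grp) != len(sol.assignments):
            raise ValueError(
                f"{tid}: {len(grp)} feature rows vs "
                f"{len(sol.assignments)} assignments")
        for i, row in grp.iterrows():
            tag = tags[int(sol.assignments[i])]
            perf = float(row["performance_pct"])
            rows.append((row["participant"], tid, tag, perf,
                         performance_class(perf), task_risk(tag, perf)))
    per_task = pd.DataFrame(rows, columns=[
        "participant", "task", "cognitive_tag", "performance_pct",
        "performance_class", "task_risk"])

    n_tasks = len(spec_by_id)
    gen_rows = []
    for pid, grp in per_task.groupby("participant", sort=True):
        if len(grp) != n_tasks:
            raise ValueError(f"participant {pid} has {len(grp)} tasks, "
                             f"expected {n_tasks}")
        risks = grp["task_risk"].tolist()
        low_count = risks.count("low")
        gen_rows.append((pid, low_count,
                         general_risk(risks, low_threshold, n_tasks)))
    general = pd.DataFrame(gen_rows,
                           columns=["participant", "low_count", "general_risk"])
    return RiskProfiles(per_task=per_task, general=general)
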