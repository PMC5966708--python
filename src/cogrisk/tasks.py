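"""Task specifications for the six-task BCI battery.

The default battery mirrors a protocol of three paradigms run twice each at
different difficulty levels: P300 matrix spelling (tasks ``P300/1``,
``P300/2``), steady-state visually evoked potentials (``SSVEP/1``,
``SSVEP/2``) and motor imagery (``MI/1``, ``MI/2``).  Each
:class:`TaskSpec` carries the calibration the synthetic cohort generator
draws from: two latent cognitive-state centres in feature space (a *risky*
state and a *safe* state), a global spread, feature bounds, and the task's
performance distribution.

Feature triples are ordered ``(pupil_dilation_pct, blink_rate, gsr_norm)``
throughout: percent pupil-diameter change from a 1-s onset baseline, blink
events per second, and dimensionless per-participant normalized galvanic
skin response.

The expected physiological signature of the risky cognitive state differs
by paradigm: cognitively loading tasks (P300 spelling, feedback-driven
motor imagery) make mental *overload* the risk, signalled by pupil
dilation and raised skin conductance; monotonous tasks (SSVEP fixation,
plain motor imagery) make *drowsiness* the risk, signalled by pupil
constriction and lowered conductance.  :attr:`TaskSpec.risky_direction`
records which regime a task belongs to, and ``expected_risky_sign`` the
per-feature direction used as a tagging tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

Triple = Tuple[float, float, float]

FEATURE_NAMES = ("pupil_pct", "blink_rate", "gsr_norm")


class TaskType(str, Enum):
    P300 = "P300"
    SSVEP = "SSVEP"
    MI1 = "MI1"
    MI2 = "MI2"


class RiskyDirection(str, Enum):
    """Which cognitive state a task renders hazardous."""

    LOADING = "loading_is_risky"
    DROWSINESS = "drowsiness_is_risky"


@dataclass(frozen=True)
class TaskSpec:
    """Calibration for one task of the battery.

    Parameters
    ----------
    task_id:
        Display identifier, e.g. ``"P300/1"``.
    task_type:
        Paradigm the task belongs to.
    duration_s:
        Task length in seconds.  Must exceed 1 s so the pupil baseline
        window fits.
    feature_center_risky, feature_center_safe:
        Latent-state centres of the feature triple.
    feature_sd:
        Global (pooled, across both states) spread of each feature.
    feature_min, feature_max:
        Hard bounds; generated features are truncated to this box.
    perf_mean, perf_sd, perf_min, perf_max:
        Truncated-normal parameters of the task-performance percentage.
    risky_direction:
        Whether mental loading or drowsiness is the hazardous state.
    expected_risky_sign:
        Per-feature sign (+1/-1) of the risky state relative to the safe
        state, used to break ties when tagging clusters.
    """

    task_id: str
    task_type: TaskType
    duration_s: float
    feature_center_risky: Triple
    feature_center_safe: Triple
    feature_sd: Triple
    feature_min: Triple
    feature_max: Triple
    perf_mean: float
    perf_sd: float
    perf_min: float
    perf_max: float
    risky_direction: RiskyDirection
    expected_risky_sign: Tuple[int, int, int] = field(default=(1, 1, 1))

    def __post_init__(self) -> None:
        if not self.duration_s > 1:
            raise ValueError(
                f"{self.task_id}: duration_s must exceed 1 s "
                "(the baseline window must fit)"
            )
        for j in range(3):
            lo, hi = self.feature_min[j], self.feature_max[j]
            for c in (self.feature_center_risky[j], self.feature_center_safe[j]):
                if not lo <= c <= hi:
                    raise ValueError(
                        f"{self.task_id}: centre {c} of feature {j} outside "
                        f"bounds [{lo}, {hi}]"
                    )
        if not (0 <= self.perf_min <= self.perf_max <= 100):
            raise ValueError(f"{self.task_id}: performance bounds outside [0, 100]")


# Default task length.  Normalized-GSR magnitudes of ~0.004 under the
# duration-normalized convention correspond to per-second conductance ratios
# near 1 when tasks run about 250 s, so that length is used for the whole
# battery.
_DUR = 250.0

#: The six-task battery with its published calibration: latent-state
#: centres, global feature spreads and bounds, and per-task performance
#: distributions.  The risky-state centre is listed first.
DEFAULT_TASKS: Tuple[TaskSpec, ...] = (
    TaskSpec(
        task_id="P300/1",
        task_type=TaskType.P300,
        duration_s=_DUR,
        feature_center_risky=(20.84, 0.08, 0.0047),
        feature_center_safe=(5.76, 0.06, 0.0046),
        feature_sd=(8.75, 0.052, 0.003),
        feature_min=(-3.72, 0.02, 0.001),
        feature_max=(36.93, 0.30, 0.02),
        perf_mean=56.29, perf_sd=32.36, perf_min=0.0, perf_max=100.0,
        risky_direction=RiskyDirection.LOADING,
        expected_risky_sign=(1, 1, 1),
    ),
    TaskSpec(
        task_id="P300/2",
        task_type=TaskType.P300,
        duration_s=_DUR,
        feature_center_risky=(32.36, 0.07, 0.0058),
        feature_center_safe=(11.41, 0.09, 0.0071),
        feature_sd=(12.604, 0.07, 0.008),
        feature_min=(-9.96, 0.04, 0.003),
        feature_max=(51.95, 0.407, 0.062),
        perf_mean=29.36, perf_sd=25.87, perf_min=0.0, perf_max=88.89,
        risky_direction=RiskyDirection.LOADING,
        # denser stimulation is expected to suppress blinking under load
        expected_risky_sign=(1, -1, 1),
    ),
    TaskSpec(
        task_id="SSVEP/1",
        task_type=TaskType.SSVEP,
        duration_s=_DUR,
        feature_center_risky=(-7.21, 0.05, 0.004),
        feature_center_safe=(32.99, 0.15, 0.0085),
        feature_sd=(12.069, 0.062, 0.003),
        feature_min=(-23.67, 0.02, 0.0003),
        feature_max=(50.68, 0.257, 0.024),
        perf_mean=70.99, perf_sd=9.95, perf_min=53.0, perf_max=100.0,
        risky_direction=RiskyDirection.DROWSINESS,
        expected_risky_sign=(-1, -1, -1),
    ),
    TaskSpec(
        task_id="SSVEP/2",
        task_type=TaskType.SSVEP,
        duration_s=_DUR,
        feature_center_risky=(-10.55, 0.04, 0.0044),
        feature_center_safe=(5.59, 0.07, 0.0042),
        feature_sd=(9.409, 0.04, 0.002),
        feature_min=(-31.75, 0.017, 0.0004),
        feature_max=(28.37, 0.224, 0.022),
        perf_mean=71.21, perf_sd=9.25, perf_min=56.0, perf_max=100.0,
        risky_direction=RiskyDirection.DROWSINESS,
        expected_risky_sign=(-1, -1, -1),
    ),
    TaskSpec(
        task_id="MI/1",
        task_type=TaskType.MI1,
        duration_s=_DUR,
        feature_center_risky=(-7.35, 0.04, 0.0039),
        feature_center_safe=(7.76, 0.10, 0.0041),
        feature_sd=(9.026, 0.104, 0.002),
        feature_min=(-23.28, 0.02, 0.001),
        feature_max=(22.16, 0.48, 0.01),
        perf_mean=75.66, perf_sd=3.94, perf_min=68.0, perf_max=85.0,
        risky_direction=RiskyDirection.DROWSINESS,
        expected_risky_sign=(-1, -1, -1),
    ),
    TaskSpec(
        task_id="MI/2",
        task_type=TaskType.MI2,
        duration_s=_DUR,
        feature_center_risky=(14.82, 0.07, 0.0048),
        feature_center_safe=(-1.48, 0.05, 0.004),
        feature_sd=(9.589, 0.067, 0.002),
        feature_min=(-20.62, 0.02, 0.001),
        feature_max=(40.63, 0.35, 0.021),
        perf_mean=76.76, perf_sd=6.72, perf_min=70.0, perf_max=100.0,
        risky_direction=RiskyDirection.LOADING,
        expected_risky_sign=(1, 1, 1),
    ),
)

DEFAULT_TASK_IDS: Tuple[str, ...] = tuple(t.task_id for t in DEFAULT_TASKS)


def task_by_id(task_id: str, tasks=DEFAULT_TASKS) -> TaskSpec:
    for t in tasks:
        if t.task_id == task_id:
            return t
    raise KeyError(f"unknown task_id {task_id!r}")
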