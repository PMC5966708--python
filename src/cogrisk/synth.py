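"""Synthetic cohorts of raw physiological signals with a latent two-state structure.

Every downstream stage of the pipeline (feature extraction, clustering,
risk tagging, consistency checks) is exercised on cohorts produced here.
Each participant x task cell is assigned a latent cognitive state —
*risky* or *safe* — and a feature triple (pupil dilation %, blink rate,
normalized GSR) drawn from a truncated normal around that state's centre.
:func:`invert_features_to_signals` then realises raw signals (an
eye-tracker sample stream and a per-second skin-conductance series) whose
feature extraction returns the drawn triple, so the whole pipeline can be
validated as a round trip.

Two conventions for the normalized-GSR feature are supported, differing in
whether the mean per-second conductance ratio is divided by the task
length once more (``per_second_mean_over_duration``) or not
(``per_second_mean``).

A structural caveat: normalized GSR divides each task's conductance by the
participant's overall mean across all their tasks, so only *relative* task
levels are identifiable — the duration-weighted mean of the per-second
ratios is 1 by construction for any real recording.  Arbitrary drawn GSR
targets are therefore projected onto that self-consistent subspace before
signals are built, and the projected values are stored as the latent
truth (see :func:`generate_cohort`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .tasks import DEFAULT_TASKS, FEATURE_NAMES, TaskSpec, Triple

__all__ = [
    "GeneratorConfig",
    "SessionRecording",
    "CohortDataset",
    "GenerationError",
    "ConfigurationError",
    "generate_feature_table",
    "invert_features_to_signals",
    "generate_cohort",
    "write_cohort",
]

#: nominal eye-tracker sampling cadence (one sample per 17 ms)
SAMPLE_INTERVAL_MS = 17


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """Signal synthesis could not realise the requested targets."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the calibration cohort: 70 participants, the six-task
    battery, an even latent mixture, per-cluster spread equal to
    ``cluster_sd_fraction`` of the published global spread (0.15, chosen so
    two-means clustering on the generated features attains silhouette
    scores in the published 0.59-0.78 range and recovers the latent states
    reliably), and the duration-normalized GSR convention whose magnitudes
    match the published feature tables.
    """

    n_participants: int = 70
    tasks: Tuple[TaskSpec, ...] = DEFAULT_TASKS
    seed: int = 0
    noise_scale: float = 1.0
    mixture_weight: float = 0.5
    gsr_convention: str = "per_second_mean_over_duration"
    cluster_sd_fraction: float = 0.15
    #: probability that a participant's six tasks share one latent draw
    #: instead of drawing independently (cross-task dependence switch)
    participant_coupling: float = 0.0
    baseline_pupil_mm: float = 4.0
    blink_run_len: int = 8
    #: participant-level mean skin conductance in microsiemens
    gsr_base_level_us: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name in ("noise_scale", "mixture_weight", "participant_coupling",
                     "baseline_pupil_mm", "gsr_base_level_us"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v}")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        if not 0 <= self.mixture_weight <= 1:
            raise ConfigurationError("mixture_weight must be in [0, 1]")
        if not 0 <= self.participant_coupling <= 1:
            raise ConfigurationError("participant_coupling must be in [0, 1]")
        if self.gsr_convention not in ("per_second_mean",
                                       "per_second_mean_over_duration"):
            raise ConfigurationError(
                f"unknown gsr_convention {self.gsr_convention!r}")
        if self.blink_run_len < 1:
            raise ConfigurationError("blink_run_len must be >= 1")
        if not self.tasks:
            raise ConfigurationError("tasks must be nonempty")


@dataclass
class SessionRecording:
    """Raw signals for one participant x task.

    ``pupil_mm`` holds NaN where the eye tracker lost the pupil (blinks);
    ``gsr_series`` holds one conductance value (µS) per elapsed second.
    """

    participant_id: str
    task_id: str
    timestamps_ms: np.ndarray
    pupil_mm: np.ndarray
    gsr_series: np.ndarray
    duration_s: float
    performance_pct: float

    def __post_init__(self) -> None:
        if len(self.timestamps_ms) != len(self.pupil_mm):
            raise ValueError("timestamp/diameter length mismatch")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("pupil timestamps must be strictly increasing")
        if np.any(self.gsr_series <= 0):
            raise ValueError("GSR series must be strictly positive")
        if not 0 <= self.performance_pct <= 100:
            raise ValueError("performance_pct outside [0, 100]")


@dataclass
class CohortDataset:
    """A full synthetic cohort.

    ``latent_features`` holds the realised feature truth per cell — the
    drawn triples after blink-count quantisation and GSR self-consistency
    projection — which feature extraction on ``recordings`` reproduces.
    """

    recordings: Dict[Tuple[str, str], SessionRecording]
    latent_labels: pd.DataFrame
    latent_features: pd.DataFrame
    config: GeneratorConfig


def _participant_ids(n: int) -> List[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _trunc_draw(rng: np.random.Generator, mu: float, sd: float,
                lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, min(max(mu, lo), hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                         random_state=rng)


def generate_feature_table(
    config: GeneratorConfig, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the feature-level cohort (fast path, no raw signals).

    For each participant x task the latent state is Bernoulli
    (``mixture_weight`` = probability of the risky state) and the feature
    triple is truncated-normal around that state's centre with spread
    ``noise_scale * cluster_sd_fraction * global sd``, truncated to the
    task's feature box.  Task performance is truncated-normal with the
    task's published moments, independent of the latent state.

    Returns
    -------
    features : DataFrame
        Columns ``participant, task, pupil_pct, blink_rate, gsr_norm,
        performance_pct``; one row per participant x task.
    labels : DataFrame
        Columns ``participant, task, latent_state`` with values
        ``"risky"``/``"safe"``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pids = _participant_ids(config.n_participants)
    n = len(pids)
    w = config.mixture_weight

    # participant-level shared draw for the optional cross-task coupling
    shared_risky = rng.random(n) < w
    rows, label_rows = [], []
    for spec in config.tasks:
        use_shared = rng.random(n) < config.participant_coupling
        indep_risky = rng.random(n) < w
        risky = np.where(use_shared, shared_risky, indep_risky)
        feats = np.empty((n, 3))
        for j in range(3):
            sd = config.noise_scale * config.cluster_sd_fraction * spec.feature_sd[j]
            lo, hi = spec.feature_min[j], spec.feature_max[j]
            for state, centre in ((True, spec.feature_center_risky),
                                  (False, spec.feature_center_safe)):
                idx = np.where(risky == state)[0]
                if idx.size:
                    feats[idx, j] = _trunc_draw(rng, centre[j], sd, lo, hi,
                                                idx.size)
        perf = _trunc_draw(rng, spec.perf_mean, spec.perf_sd,
                           spec.perf_min, spec.perf_max, n)
        for i, pid in enumerate(pids):
            rows.append((pid, spec.task_id, *feats[i], perf[i]))
            label_rows.append((pid, spec.task_id,
                               "risky" if risky[i] else "safe"))

    features = pd.DataFrame(
        rows, columns=["participant", "task", *FEATURE_NAMES, "performance_pct"]
    )
    labels = pd.DataFrame(label_rows,
                          columns=["participant", "task", "latent_state"])
    order = {t.task_id: k for k, t in enumerate(config.tasks)}
    for df in (features, labels):
        df["_o"] = df["task"].map(order)
    features = (features.sort_values(["participant", "_o"], kind="stable")
                .drop(columns="_o").reset_index(drop=True))
    labels = (labels.sort_values(["participant", "_o"], kind="stable")
              .drop(columns="_o").reset_index(drop=True))
    return features, labels


def invert_features_to_signals(
    target: Triple,
    spec: TaskSpec,
    seed: int,
    *,
    participant_id: str = "P01",
    performance_pct: float = 100.0,
    baseline_mm: float = 4.0,
    overall_gsr_mean: float = 1.0,
    gsr_convention: str = "per_second_mean",
    blink_run_len: int = 8,
) -> SessionRecording:
    """Construct raw signals whose feature extraction returns ``target``.

    The pupil stream holds a constant ``baseline_mm`` during the first
    second and a constant ``baseline_mm * (1 + pupil_pct/100)`` afterwards.
    Blinks are realised as ``round(blink_rate * duration_s)`` contiguous
    runs of ``blink_run_len`` missing samples placed uniformly at random
    (non-touching, so run count is preserved) after the baseline second.
    The GSR series is a constant level such that the chosen normalization
    convention, evaluated against ``overall_gsr_mean``, returns the target.

    The blink-rate component is quantised to a whole number of events;
    pupil and GSR components are recovered exactly.
    """
    pupil_pct, blink_rate, gsr_norm = target
    if pupil_pct <= -100:
        raise GenerationError("pupil target must exceed -100%")
    if blink_rate < 0 or gsr_norm <= 0 or overall_gsr_mean <= 0:
        raise GenerationError("blink target must be >= 0 and GSR targets > 0")
    rng = np.random.default_rng(seed)
    duration_s = int(round(spec.duration_s))
    n_samples = int(duration_s * 1000 // SAMPLE_INTERVAL_MS) + 1
    t = np.arange(n_samples, dtype=np.int64) * SAMPLE_INTERVAL_MS
    pupil = np.where(t < 1000, baseline_mm,
                     baseline_mm * (1 + pupil_pct / 100.0)).astype(float)

    n_events = int(round(blink_rate * duration_s))
    if n_events > 0:
        i0 = int(np.searchsorted(t, 1000))  # first remainder sample
        r = n_samples - i0
        run = blink_run_len
        # runs must not touch (a merged run would count as one event) and
        # at least one valid remainder sample must survive
        free = r - n_events * run - (n_events - 1)
        if free < 1:
            raise GenerationError(
                f"{spec.task_id}: cannot place {n_events} blink runs of "
                f"{run} samples in {r} remainder samples; use a longer duration"
            )
        u = np.sort(rng.choice(free + n_events, size=n_events, replace=False))
        gaps = u - np.arange(n_events)
        starts = i0 + gaps + np.arange(n_events) * (run + 1)
        for s in starts:
            pupil[s:s + run] = np.nan

    ratio = gsr_norm * duration_s if gsr_convention == "per_second_mean_over_duration" else gsr_norm
    level = ratio * overall_gsr_mean
    gsr = np.full(duration_s, level)

    return SessionRecording(
        participant_id=participant_id,
        task_id=spec.task_id,
        timestamps_ms=t,
        pupil_mm=pupil,
        gsr_series=gsr,
        duration_s=float(duration_s),
        performance_pct=performance_pct,
    )


def _project_gsr(targets: np.ndarray, durations: np.ndarray,
                 convention: str) -> Tuple[np.ndarray, np.ndarray]:
    """Scale a participant's GSR targets onto the identifiable subspace.

    Returns the projected targets and the per-second conductance ratios
    whose duration-weighted mean is exactly 1.
    """
    ratios = targets * durations if convention == "per_second_mean_over_duration" else targets.copy()
    c = float(np.sum(ratios * durations) / np.sum(durations))
    if c <= 0:
        raise GenerationError("nonpositive GSR target combination")
    ratios = ratios / c
    projected = ratios / durations if convention == "per_second_mean_over_duration" else ratios
    return projected, ratios


def generate_cohort(config: GeneratorConfig,
                    seed: Optional[int] = None) -> CohortDataset:
    """Draw a feature-level cohort and realise raw signals for every cell.

    ``latent_features`` stores the realised truth: blink rates quantised to
    whole event counts and GSR targets projected per participant so the
    normalization identity (duration-weighted mean ratio = 1) holds.
    Feature extraction applied to ``recordings`` reproduces this table to
    numerical precision.
    """
    if seed is None:
        seed = config.seed
    features, labels = generate_feature_table(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    recordings: Dict[Tuple[str, str], SessionRecording] = {}
    realized = features.copy()
    durations = np.array([float(int(round(t.duration_s))) for t in config.tasks])
    spec_by_id = {t.task_id: t for t in config.tasks}
    for pid, grp in features.groupby("participant", sort=False):
        grp = grp.set_index("task").loc[[t.task_id for t in config.tasks]]
        projected, ratios = _project_gsr(grp["gsr_norm"].to_numpy(),
                                         durations, config.gsr_convention)
        for j, spec in enumerate(config.tasks):
            row = grp.iloc[j]
            rec = invert_features_to_signals(
                (row["pupil_pct"], row["blink_rate"], projected[j]),
                spec,
                seed=int(rng.integers(2 ** 31)),
                participant_id=pid,
                performance_pct=float(row["performance_pct"]),
                baseline_mm=config.baseline_pupil_mm,
                overall_gsr_mean=config.gsr_base_level_us,
                gsr_convention=config.gsr_convention,
                blink_run_len=config.blink_run_len,
            )
            recordings[(pid, spec.task_id)] = rec
            mask = (realized["participant"] == pid) & (realized["task"] == spec.task_id)
            dur = durations[j]
            realized.loc[mask, "gsr_norm"] = projected[j]
            realized.loc[mask, "blink_rate"] = round(row["blink_rate"] * dur) / dur
    return CohortDataset(recordings=recordings, latent_labels=labels,
                         latent_features=realized, config=config)


def _slug(task_id: str) -> str:
    return task_id.replace("/", "-")


def write_cohort(cohort: CohortDataset, out_dir) -> Path:
    """Write a cohort to ``out_dir`` as plain-text files.

    Per participant x task: an eye-tracker TSV (``timestamp_ms``,
    ``pupil_mm``; empty field = missing sample) and a GSR CSV (``second``,
    ``microsiemens``).  Cohort-level: ``performance.csv``,
    ``latent_labels.csv``, ``latent_features.csv`` and ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (pid, tid), rec in cohort.recordings.items():
        base = out / f"{pid}_{_slug(tid)}"
        with open(f"{base}_pupil.tsv", "w") as fh:
            fh.write("timestamp_ms\tpupil_mm\n")
            for ts, d in zip(rec.timestamps_ms, rec.pupil_mm):
                fh.write(f"{ts}\t{'' if np.isnan(d) else repr(float(d))}\n")
        with open(f"{base}_gsr.csv", "w") as fh:
            fh.write("second,microsiemens\n")
            for s, g in enumerate(rec.gsr_series):
                fh.write(f"{s},{float(g)!r}\n")
    perf = cohort.latent_features[["participant", "task", "performance_pct"]]
    perf.to_csv(out / "performance.csv", index=False)
    cohort.latent_labels.to_csv(out / "latent_labels.csv", index=False)
    cohort.latent_features.to_csv(out / "latent_features.csv", index=False)
    cfg = {k: v for k, v in vars(cohort.config).items() if k != "tasks"}
    cfg["tasks"] = [
        {**{k: (list(v) if isinstance(v, tuple) else
                v.value if hasattr(v, "value") else v)
            for k, v in vars(t).items()}}
        for t in cohort.config.tasks
    ]
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out
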