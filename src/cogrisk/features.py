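"""Physiological feature extraction from raw eye-tracker and GSR signals.

Three features are computed per participant x task:

* **Pupil dilation (%)** — percent change of the mean pupil diameter in
  the task remainder relative to the mean over the first second (the
  onset baseline).  Missing samples (blinks / track loss) are excluded
  from both means.
* **Blink rate (1/s)** — blinks are read off the eye-tracker stream as
  runs of missing samples.  Two counting conventions exist: ``events``
  counts maximal contiguous missing runs (one blink = one run, the
  default) and ``lines`` counts individual missing samples, which at a
  17 ms cadence counts a single ~140 ms blink several times over.
* **Normalized GSR** — each second's skin conductance is divided by the
  participant's mean conductance pooled over *all* their tasks; the
  per-second ratios are averaged over the task.  Under the
  ``per_second_mean_over_duration`` convention that mean is divided by
  the task length once more, giving the ~1/duration magnitudes some
  published feature tables report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .synth import CohortDataset, SessionRecording
from .tasks import FEATURE_NAMES

__all__ = [
    "ExtractionError",
    "FeatureVector",
    "pupil_dilation_pct",
    "blink_rate",
    "participant_overall_gsr_mean",
    "gsr_normalized",
    "build_feature_table",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
]


class ExtractionError(ValueError):
    """A feature could not be computed from the given signals."""


@dataclass(frozen=True)
class FeatureVector:
    participant_id: str
    task_id: str
    pupil_pct: float
    blink_rate: float
    gsr_norm: float

    def __post_init__(self) -> None:
        if self.blink_rate < 0 or self.gsr_norm <= 0 or self.pupil_pct <= -100:
            raise ValueError("feature vector outside physiological range")


def pupil_dilation_pct(timestamps_ms: np.ndarray, pupil_mm: np.ndarray,
                       baseline_window_s: float = 1.0) -> float:
    """Percent pupil-diameter change of the task remainder vs the onset baseline.

    The baseline is the closed-open window ``[0, baseline_window_s)`` in
    task time; the remainder is everything after it.  NaN samples are
    excluded from both means.
    """
    t = np.asarray(timestamps_ms, dtype=float)
    d = np.asarray(pupil_mm, dtype=float)
    valid = np.isfinite(d)
    in_base = t < baseline_window_s * 1000.0
    base = d[valid & in_base]
    rest = d[valid & ~in_base]
    if base.size == 0:
        raise ExtractionError(
            f"no valid pupil sample in the [0, {baseline_window_s}) s baseline window")
    if rest.size == 0:
        raise ExtractionError(
            f"no valid pupil sample after the {baseline_window_s} s baseline window")
    mb = base.mean()
    if mb == 0:
        raise ExtractionError("baseline mean diameter is zero")
    return 100.0 * (rest.mean() - mb) / mb


def blink_rate(pupil_mm: np.ndarray, duration_s: float,
               convention: str = "events") -> float:
    """Blink rate from missing eye-tracker samples.

    ``events`` counts maximal contiguous runs of missing samples;
    ``lines`` counts every missing sample.  Either count is divided by
    the task duration in seconds.
    """
    if duration_s <= 0:
        raise ExtractionError("duration_s must be positive")
    missing = ~np.isfinite(np.asarray(pupil_mm, dtype=float))
    if convention == "lines":
        count = int(missing.sum())
    elif convention == "events":
        # a run starts where missing turns on
        starts = missing & ~np.concatenate(([False], missing[:-1]))
        count = int(starts.sum())
    else:
        raise ValueError(f"unknown blink convention {convention!r}")
    return count / duration_s


def participant_overall_gsr_mean(all_task_series: Iterable[np.ndarray]) -> float:
    """Mean conductance pooled over all per-second values of all the
    participant's tasks (longer tasks weigh proportionally more)."""
    series = [np.asarray(s, dtype=float) for s in all_task_series]
    if not series or sum(s.size for s in series) == 0:
        raise ExtractionError("no GSR data supplied")
    pooled = np.concatenate(series)
    if np.any(pooled <= 0):
        raise ExtractionError("GSR series must be strictly positive")
    return float(pooled.mean())


def gsr_normalized(task_series: np.ndarray, overall_mean: float,
                   duration_s: float | None = None,
                   convention: str = "per_second_mean") -> float:
    """Task-level normalized GSR.

    Each second's value is divided by the participant's overall mean; the
    ratios are summed and divided by the task length
    (``per_second_mean``), and under ``per_second_mean_over_duration``
    divided by the task length a second time.
    """
    s = np.asarray(task_series, dtype=float)
    if overall_mean <= 0:
        raise ExtractionError("overall_mean must be positive")
    if duration_s is None:
        duration_s = float(s.size)
    if duration_s <= 0:
        raise ExtractionError("duration_s must be positive")
    value = float(np.sum(s / overall_mean) / duration_s)
    if convention == "per_second_mean_over_duration":
        value /= duration_s
    elif convention != "per_second_mean":
        raise ValueError(f"unknown GSR convention {convention!r}")
    return value


def build_feature_table(cohort: CohortDataset,
                        blink_convention: str = "events") -> pd.DataFrame:
    """Extract the three features for every recording of a cohort.

    The participant's overall GSR mean is pooled across all their tasks;
    the GSR convention is taken from the cohort's generator config.
    Returns a DataFrame with columns ``participant, task, pupil_pct,
    blink_rate, gsr_norm, performance_pct``.
    """
    config = cohort.config
    task_ids = [t.task_id for t in config.tasks]
    pids = sorted({pid for pid, _ in cohort.recordings})
    rows = []
    for pid in pids:
        recs = []
        for tid in task_ids:
            rec = cohort.recordings.get((pid, tid))
            if rec is None:
                raise ExtractionError(f"missing recording for {pid} / {tid}")
            recs.append(rec)
        overall = participant_overall_gsr_mean([r.gsr_series for r in recs])
        for rec in recs:
            try:
                p = pupil_dilation_pct(rec.timestamps_ms, rec.pupil_mm)
                b = blink_rate(rec.pupil_mm, rec.duration_s, blink_convention)
                g = gsr_normalized(rec.gsr_series, overall, rec.duration_s,
                                   config.gsr_convention)
            except ExtractionError as exc:
                raise ExtractionError(
                    f"{rec.participant_id} / {rec.task_id}: {exc}") from exc
            rows.append((rec.participant_id, rec.task_id, p, b, g,
                         rec.performance_pct))
    return pd.DataFrame(
        rows, columns=["participant", "task", *FEATURE_NAMES, "performance_pct"])


def read_recording(pupil_tsv, gsr_csv, *, participant_id: str, task_id: str,
                   performance_pct: float = 100.0) -> SessionRecording:
    """Read one session from the generator's on-disk format.

    The eye-tracker TSV has columns ``timestamp_ms`` and ``pupil_mm``
    with an empty field marking a missing sample; the GSR CSV has columns
    ``second`` and ``microsiemens``.
    """
    pupil = pd.read_csv(pupil_tsv, sep="\t")
    gsr = pd.read_csv(gsr_csv)
    t = pupil["timestamp_ms"].to_numpy(dtype=np.int64)
    d = pupil["pupil_mm"].to_numpy(dtype=float)  # empty fields parse as NaN
    g = gsr.sort_values("second")["microsiemens"].to_numpy(dtype=float)
    duration = float(len(g))
    return SessionRecording(participant_id=participant_id, task_id=task_id,
                            timestamps_ms=t, pupil_mm=d, gsr_series=g,
                            duration_s=duration, performance_pct=performance_pct)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
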