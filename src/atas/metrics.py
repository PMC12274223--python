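"""The 13 temporal fluency metrics computed from a detected event sequence.

Speech rate uses the full trimmed recording duration (vocal + pause time) as
its denominator: the word count is fixed by the read passage, so the gross
words-per-minute rate is the quantity that lets increased pausing — rather
than a slower articulatory rate — show up as a slower speech rate.

Variability metrics are coefficients of variation (sample SD / mean, n-1
denominator), which makes them invariant to the unit the durations are
measured in. Statistics of an empty or singleton subset are emitted as
missing (NaN), never as zero, so they cannot corrupt group-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .detection import LONG, SHORT, EventSequence

DEFAULT_WORD_COUNT = 236  # words in the standard oral-reading passage

#: fixed metric column order used in every table this package writes
METRIC_COLUMNS = [
    "speech_rate_wpm",
    "total_pause_time_s",
    "pause_count",
    "mean_pause_ms",
    "mean_vocal_ms",
    "pause_cv",
    "vocal_cv",
    "mean_long_pause_ms",
    "mean_short_pause_ms",
    "long_pause_cv",
    "short_pause_cv",
    "long_pause_count",
    "short_pause_count",
]

COVARIATE_COLUMNS = ["participant_id", "group", "sex", "age", "percent_ss"]


@dataclass(frozen=True)
class MetricSet:
    speech_rate_wpm: float
    total_pause_time_s: float
    pause_count: int
    mean_pause_ms: float
    mean_vocal_ms: float
    pause_cv: float
    vocal_cv: float
    mean_long_pause_ms: float
    mean_short_pause_ms: float
    long_pause_cv: float
    short_pause_cv: float
    long_pause_count: int
    short_pause_count: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else float("nan")


def _cv(x: np.ndarray) -> float:
    """Sample coefficient of variation; NaN below n = 2."""
    if x.size < 2:
        return float("nan")
    m = float(np.mean(x))
    if m == 0.0:
        return float("nan")
    return float(np.std(x, ddof=1) / m)


def compute_metrics(events: EventSequence, word_count: int = DEFAULT_WORD_COUNT,
                    duration_s: float | None = None) -> MetricSet:
    """Compute the 13 metrics for one recording.

    Parameters
    ----------
    events : EventSequence
        Detected (or ground-truth) events.
    word_count : int
        Number of words in the read passage (236 for the standard passage).
    duration_s : float, optional
        Trimmed recording duration; defaults to the sequence's own duration.
    """
    if word_count < 1:
        raise ValueError("word_count must be >= 1")
    if duration_s is None:
        duration_s = events.signal_duration_s
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")

    pauses = np.array([e.duration_ms for e in events.pauses()])
    vocals = np.array([e.duration_ms for e in events.vocals()])
    long_p = np.array([e.duration_ms for e in events.pauses(LONG)])
    short_p = np.array([e.duration_ms for e in events.pauses(SHORT)])

    return MetricSet(
        speech_rate_wpm=word_count / (duration_s / 60.0),
        total_pause_time_s=float(pauses.sum()) / 1000.0,
        pause_count=int(pauses.size),
        mean_pause_ms=_mean(pauses),
        mean_vocal_ms=_mean(vocals),
        pause_cv=_cv(pauses),
        vocal_cv=_cv(vocals),
        mean_long_pause_ms=_mean(long_p),
        mean_short_pause_ms=_mean(short_p),
        long_pause_cv=_cv(long_p),
        short_pause_cv=_cv(short_p),
        long_pause_count=int(long_p.size),
        short_pause_count=int(short_p.size),
    )


def metrics_table(metric_sets: dict[str, MetricSet],
                  covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble per-recording metrics (plus optional covariates) into a cohort table.

    ``covariates`` must carry ``participant_id`` and may carry group, sex, age
    and percent_ss; missing values are propagated explicitly.
    """
    if len(metric_sets) < 1:
        raise ValueError("need at least one recording")
    ids = list(metric_sets)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    rows = [{"participant_id": pid, **ms.as_dict()} for pid, ms in metric_sets.items()]
    table = pd.DataFrame(rows)
    if covariates is not None:
        if covariates["participant_id"].duplicated().any():
            raise ValueError("duplicate participant ids in covariates")
        table = covariates.merge(table, on="participant_id", how="right")
    cols = [c for c in COVARIATE_COLUMNS if c in table.columns] + METRIC_COLUMNS
    return table[cols]
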