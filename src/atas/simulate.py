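"""Synthetic fixtures: utterance audio with ground-truth events, and cohorts.

Two generators make the whole pipeline testable without recordings:

* :func:`make_synthetic_utterance` renders an alternating voiced/silent
  interval plan as audio (440-Hz tone bursts by default, so the
  zero-crossing rate is analytically predictable; a noise-burst mode exists
  for robustness checks), with optional ambient noise and exact ground-truth
  event annotations.
* :func:`make_synthetic_cohort` draws per-participant metric tables with the
  two-group structure of the study cohort (17 adults who stutter, 18 who do
  not), either directly from group means/SDs ("table" mode) or by generating
  event sequences first and computing metrics from them ("mechanistic" mode,
  which induces realistic within-participant metric correlations and also
  yields the event sequences the sequence classifier needs).

Group moments default to the published cohort descriptives (e.g. speech rate
163.12 +/- 23.43 wpm for AWNS vs 127.60 +/- 38.11 for AWS); count metrics use
a negative binomial with the published dispersion scale (alpha ~ 0.13-0.18).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.stats import truncnorm

from .audio import AudioSignal
from .detection import (
    NONSILENT,
    SILENT,
    DetectionConfig,
    EventSequence,
    classify_events,
)
from .metrics import METRIC_COLUMNS, compute_metrics

VOICED = "voiced"
SILENT_IV = "silent"

_RAMP_MS = 5.0


# ---------------------------------------------------------------------------
# utterance audio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtteranceSpec:
    """Plan for one synthetic utterance: alternating voiced/silent intervals."""

    intervals: tuple[tuple[str, float], ...]  # (kind, duration_ms)
    voiced_mode: str = "tone"  # "tone" | "noise_burst"
    tone_hz: float = 440.0
    voiced_amplitude: float = 0.8
    ambient_noise_amplitude: float = 0.0
    sample_rate: int = 16000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        for kind, dur in self.intervals:
            if kind not in (VOICED, SILENT_IV):
                raise ValueError(f"bad interval kind {kind!r}")
            if dur <= 0:
                raise ValueError("interval durations must be positive")
        if not (0.0 < self.voiced_amplitude <= 1.0):
            raise ValueError("voiced amplitude must be in (0, 1]")
        if not (0.0 <= self.ambient_noise_amplitude <= 0.5):
            raise ValueError("ambient noise amplitude must be in [0, 0.5]")
        if self.ambient_noise_amplitude > 0 and \
                self.voiced_amplitude <= 4.0 * self.ambient_noise_amplitude:
            raise ValueError(
                "detectability guarantee requires voiced amplitude > 4x ambient")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.intervals) / 1000.0


def make_synthetic_utterance(spec: UtteranceSpec,
                             config: DetectionConfig | None = None
                             ) -> tuple[AudioSignal, EventSequence]:
    """Render ``spec`` as audio and return it with ground-truth events.

    Voiced intervals carry 5-ms raised-cosine onset/offset ramps *inside* the
    interval (a ramped sine still crosses zero, so the whole interval is
    non-silent and the exact interval edges are the ground-truth boundaries).
    Ground truth is produced by running the detector's own temporal
    thresholding on the exact intervals, so sub-threshold intervals are
    absorbed the same way the detector would absorb them.
    """
    config = config or DetectionConfig()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    pieces: list[np.ndarray] = []
    regions: list[tuple[str, float, float]] = []
    t = 0.0
    n_ramp = int(round(_RAMP_MS / 1000.0 * sr))
    for kind, dur_ms in spec.intervals:
        n = int(round(dur_ms / 1000.0 * sr))
        if kind == VOICED:
            if spec.voiced_mode == "tone":
                tt = np.arange(n) / sr
                x = spec.voiced_amplitude * np.sin(2 * np.pi * spec.tone_hz * tt)
            else:
                # sign-alternating noise: a crossing between every sample
                # pair, so detected region edges are exact on the hop grid
                x = spec.voiced_amplitude * rng.uniform(0.2, 1.0, size=n)
                x *= (-1.0) ** np.arange(n)
            k = min(n_ramp, n // 2)
            if k > 0:
                ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / k))
                x[:k] *= ramp
                x[-k:] *= ramp[::-1]
            pieces.append(x)
            regions.append((NONSILENT, t, t + n / sr))
        else:
            pieces.append(np.zeros(n))
            regions.append((SILENT, t, t + n / sr))
        t += n / sr
    samples = np.concatenate(pieces)
    if spec.ambient_noise_amplitude > 0:
        samples = samples + rng.uniform(
            -spec.ambient_noise_amplitude, spec.ambient_noise_amplitude,
            size=samples.size)
    signal = AudioSignal(samples=samples, sample_rate=sr)
    truth = classify_events(regions, config, signal_duration_s=signal.duration_s)
    return signal, truth


def random_utterance_spec(rng: np.random.Generator, noisy: bool = False,
                          boundary_cases: bool = False,
                          sample_rate: int = 16000) -> UtteranceSpec:
    """Draw a random detectable utterance plan (for recovery property tests).

    Durations are integer milliseconds at least twice their temporal
    threshold. Noisy specs keep pause durations >= 20 ms away from the 150-ms
    short/long boundary (denoising legitimately blurs edges by a few ms);
    clean specs may place pauses exactly at 150/151 ms to exercise the
    boundary.
    """
    n_pauses = int(rng.integers(2, 6))
    mode = "noise_burst" if (boundary_cases and not noisy) else "tone"
    intervals: list[tuple[str, float]] = []
    for i in range(n_pauses + 1):
        intervals.append((VOICED, float(rng.integers(220, 901))))
        if i < n_pauses:
            if boundary_cases and not noisy and rng.random() < 0.5:
                dur = float(rng.choice([150, 151]))
            elif noisy:
                dur = float(rng.choice([rng.integers(100, 131),
                                        rng.integers(170, 701)]))
            else:
                # a 440-Hz tone's crossings are ~1.1 ms apart, so detected
                # pauses may run up to ~2.4 ms long; keep clean tone pauses
                # out of the (147, 150] sliver where that could flip the
                # short/long subtype
                dur = float(rng.choice([rng.integers(100, 148),
                                        rng.integers(151, 701)]))
            intervals.append((SILENT_IV, dur))
    ambient = float(rng.uniform(0.02, 0.05)) if noisy else 0.0
    amp = float(rng.uniform(max(0.3, 4.5 * ambient), 0.9))
    return UtteranceSpec(intervals=tuple(intervals), voiced_mode=mode,
                         voiced_amplitude=amp,
                         ambient_noise_amplitude=ambient,
                         sample_rate=sample_rate,
                         seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: published cohort descriptives: continuous metrics as (mean, SD), count
#: metrics as (mean, NB2 dispersion alpha)
GROUP_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "AWNS": {
        "speech_rate_wpm": (163.12, 23.43),
        "total_pause_time_s": (16.48, 4.68),
        "mean_pause_ms": (286.51, 62.15),
        "mean_vocal_ms": (1258.14, 226.64),
        "pause_cv": (0.89, 0.11),
        "vocal_cv": (0.74, 0.07),
        "mean_long_pause_ms": (450.99, 75.42),
        "mean_short_pause_ms": (86.01, 5.36),
        "long_pause_cv": (0.53, 0.08),
        "short_pause_cv": (0.33, 0.03),
        "long_pause_count": (31.11, 0.18),
        "short_pause_count": (26.89, 0.13),
    },
    "AWS": {
        "speech_rate_wpm": (127.60, 38.11),
        "total_pause_time_s": (30.68, 22.40),
        "mean_pause_ms": (338.14, 84.40),
        "mean_vocal_ms": (1250.82, 358.11),
        "pause_cv": (0.90, 0.16),
        "vocal_cv": (0.82, 0.10),
        "mean_long_pause_ms": (484.02, 108.23),
        "mean_short_pause_ms": (90.41, 6.57),
        "long_pause_cv": (0.61, 0.18),
        "short_pause_cv": (0.31, 0.04),
        "long_pause_count": (55.12, 0.18),
        "short_pause_count": (31.35, 0.13),
    },
}

COUNT_METRICS = ("long_pause_count", "short_pause_count")

#: physical truncation bounds for the continuous metrics
_BOUNDS: dict[str, tuple[float, float]] = {
    "speech_rate_wpm": (1.0, np.inf),
    "total_pause_time_s": (0.0, np.inf),
    "mean_pause_ms": (50.0, np.inf),
    "mean_vocal_ms": (100.0, np.inf),
    "pause_cv": (0.0, np.inf),
    "vocal_cv": (0.0, np.inf),
    "mean_long_pause_ms": (150.0, np.inf),
    "mean_short_pause_ms": (50.0, 150.0),
    "long_pause_cv": (0.0, np.inf),
    "short_pause_cv": (0.0, np.inf),
}

#: demographic models: (male count, group size, age mean, age SD, age range)
_DEMOGRAPHICS = {
    "AWNS": (10, 18, 31.78, 9.95, (22.0, 63.0)),
    "AWS": (12, 17, 39.59, 14.45, (24.0, 62.0)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a two-group cohort table."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AWNS": 18, "AWS": 17})
    moments: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_MOMENTS.items()})
    # %SS for AWS rows: intercept + slope * long_pause_count + N(0, sd)
    ss_intercept: float = 1.0
    ss_slope_per_long_pause: float = 0.09
    ss_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"need n >= 2 per group, got {n} for {g}")
        for g, mom in self.moments.items():
            for m, (mean, scale) in mom.items():
                if scale <= 0:
                    raise ValueError(f"{g}/{m}: SD/alpha must be positive")


@lru_cache(maxsize=256)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Location/scale whose truncation to [lo, hi] has the target mean and SD.

    Without this correction a marginal like AWS total pause time
    (30.68 +/- 22.40 s, truncated at 0) would come out ~3 s too high.
    """
    if not (lo < mean < hi):
        raise ValueError(
            f"infeasible truncation: mean {mean} outside bounds ({lo}, {hi})")

    def residuals(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, np.sqrt(float(v)) - sd]

    sol, info, ok, _ = fsolve(residuals, [mean, np.log(sd)], full_output=True)
    if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-6 * max(1.0, sd):
        raise ValueError(
            f"infeasible truncation: no normal truncated to ({lo}, {hi}) "
            f"has mean {mean} and SD {sd}")
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_truncnorm(rng, mean, sd, lo, hi, size, match_moments=True):
    if match_moments:
        loc, scale = _truncnorm_params(float(mean), float(sd), float(lo), float(hi))
    else:  # plain truncation (demographics: the range is part of the spec)
        loc, scale = float(mean), float(sd)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _draw_negbin(rng, mean, alpha, size):
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(int)


def _demographics(rng, group, n):
    males, n_ref, age_mean, age_sd, (lo, hi) = _DEMOGRAPHICS[group]
    sex = np.array(["male"] * n + ["female"] * 0, dtype=object)
    n_male = int(round(n * males / n_ref))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male), dtype=object)
    rng.shuffle(sex)
    age = np.round(_draw_truncnorm(rng, age_mean, age_sd, lo, hi, n,
                               match_moments=False), 1)
    return sex, age


def make_synthetic_cohort(spec: CohortSpec | None = None,
                          mode: str = "table") -> pd.DataFrame:
    """Generate a cohort metric table (one row per participant).

    ``table`` mode draws each metric from its group's truncated-normal /
    negative-binomial marginal; ``mechanistic`` mode generates an event
    sequence per participant and computes the metrics from it.
    """
    if mode == "mechanistic":
        _, table = make_synthetic_recordings(spec)
        return table
    if mode != "table":
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in spec.n_per_group.items():
        mom = spec.moments[group]
        sex, age = _demographics(rng, group, n)
        draws: dict[str, np.ndarray] = {}
        for m, (mean, scale) in mom.items():
            if m in COUNT_METRICS:
                draws[m] = _draw_negbin(rng, mean, scale, n)
            else:
                lo, hi = _BOUNDS[m]
                draws[m] = _draw_truncnorm(rng, mean, scale, lo, hi, n)
        draws["pause_count"] = draws["long_pause_count"] + draws["short_pause_count"]
        for i in range(n):
            rows.append({
                "participant_id": f"{group}_{i:03d}", "group": group,
                "sex": sex[i], "age": age[i],
                **{m: draws[m][i] for m in draws},
            })
    table = pd.DataFrame(rows)
    ss = np.full(len(table), np.nan)
    aws = table["group"] == "AWS"
    noise = rng.normal(0.0, spec.ss_noise_sd, size=int(aws.sum()))
    ss[aws.to_numpy()] = np.clip(
        spec.ss_intercept
        + spec.ss_slope_per_long_pause * table.loc[aws, "long_pause_count"]
        + noise, 0.0, 100.0)
    table["percent_ss"] = ss
    cols = ["participant_id", "group", "sex", "age", "percent_ss"] + METRIC_COLUMNS
    return table[cols]


# ---------------------------------------------------------------------------
# mechanistic mode: event sequences first, metrics derived
# ---------------------------------------------------------------------------

def _lognormal(rng, mean, cv, size, lo=0.0, hi=np.inf):
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    x = rng.lognormal(mu, np.sqrt(sigma2), size=size)
    return np.clip(x, lo + 1e-9, hi - 1e-9 if np.isfinite(hi) else np.inf)


def make_synthetic_events(group: str, rng: np.random.Generator,
                          moments: dict[str, tuple[float, float]] | None = None,
                          config: DetectionConfig | None = None) -> EventSequence:
    """Generate one participant's alternating event sequence.

    Pause counts are negative-binomial; long-pause and vocal durations are
    log-normal at the group's mean/CV; short pauses are truncated normal on
    [50, 150] ms. Short and long pauses are interleaved in random order
    between consecutive vocal events.
    """
    config = config or DetectionConfig()
    mom = moments or GROUP_MOMENTS[group]
    n_long = max(1, int(_draw_negbin(rng, *mom["long_pause_count"], 1)[0]))
    n_short = max(1, int(_draw_negbin(rng, *mom["short_pause_count"], 1)[0]))
    long_d = _lognormal(rng, mom["mean_long_pause_ms"][0], mom["long_pause_cv"][0],
                        n_long, lo=config.short_long_boundary_ms + 1.0)
    short_d = _draw_truncnorm(rng, mom["mean_short_pause_ms"][0],
                              mom["mean_short_pause_ms"][1],
                              config.pause_min_ms, config.short_long_boundary_ms,
                              n_short)
    pause_d = np.concatenate([long_d, short_d])
    rng.shuffle(pause_d)
    vocal_d = _lognormal(rng, mom["mean_vocal_ms"][0], mom["vocal_cv"][0],
                         pause_d.size + 1, lo=config.vocal_min_ms + 1.0)
    from .detection import Event, PAUSE, VOCAL
    events, t = [], 0.0
    for i, vd in enumerate(vocal_d):
        events.append(Event(kind=VOCAL, start_s=t, end_s=t + vd / 1000.0))
        t += vd / 1000.0
        if i < pause_d.size:
            events.append(Event(kind=PAUSE, start_s=t, end_s=t + pause_d[i] / 1000.0))
            t += pause_d[i] / 1000.0
    from .detection import split_pauses
    return split_pauses(
        EventSequence(events=tuple(events), signal_duration_s=t, config=config))


def make_synthetic_recordings(spec: CohortSpec | None = None,
                              word_count: int = 236
                              ) -> tuple[dict[str, EventSequence], pd.DataFrame]:
    """Mechanistic cohort: per-participant event sequences plus metric table."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, EventSequence] = {}
    rows = []
    for group, n in spec.n_per_group.items():
        sex, age = _demographics(rng, group, n)
        for i in range(n):
            pid = f"{group}_{i:03d}"
            seq = make_synthetic_events(group, rng, spec.moments[group])
            sequences[pid] = seq
            ms = compute_metrics(seq, word_count=word_count)
            rows.append({"participant_id": pid, "group": group, "sex": sex[i],
                         "age": age[i], **ms.as_dict()})
    table = pd.DataFrame(rows)
    ss = np.full(len(table), np.nan)
    aws = (table["group"] == "AWS").to_numpy()
    noise = rng.normal(0.0, spec.ss_noise_sd, size=int(aws.sum()))
    ss[aws] = np.clip(spec.ss_intercept
                      + spec.ss_slope_per_long_pause
                      * table.loc[aws, "long_pause_count"].to_numpy()
                      + noise, 0.0, 100.0)
    table["percent_ss"] = ss
    cols = ["participant_id", "group", "sex", "age", "percent_ss"] + METRIC_COLUMNS
    return sequences, table[cols]


def zero_effect_spec(seed: int = 0) -> CohortSpec:
    """A null cohort: both groups share the AWNS generating moments."""
    moments = {g: dict(GROUP_MOMENTS["AWNS"]) for g in ("AWNS", "AWS")}
    return CohortSpec(moments=moments, seed=seed)
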