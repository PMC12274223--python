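"""Pause/vocal event detection by adaptive short-time energy + ZCR thresholding.

The detector works on a preprocessed (denoised, trimmed, peak-normalized)
recording:

1. the signal is blindly cut into non-overlapping 3-s segments;
2. short-time RMS energy (RMSE) and zero-crossing rate (ZCR) are computed in
   50-ms windows advanced by 1 ms;
3. each frame is labeled silent/non-silent by comparing its RMSE to the mean
   RMSE of its 3-s segment and checking whether its ZCR is zero;
4. maximal runs of identical labels become regions; region boundaries are
   refined so a silent region spans exactly the stretch covered by
   all-silent windows;
5. temporal thresholds turn regions into events: silent regions >= 50 ms are
   pauses, non-silent regions > 100 ms are vocal events, shorter regions are
   absorbed into the running event;
6. pauses are split into short (50-150 ms) and long (> 150 ms).

All decision rules are scale-invariant: multiplying the waveform by a positive
constant leaves the detected events unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .audio import AudioSignal

SILENT = "silent"
NONSILENT = "nonsilent"

VOCAL = "vocal"
PAUSE = "pause"
SHORT = "short"
LONG = "long"
NONE = "none"

_EPS_MS = 1e-6  # tolerance for threshold comparisons on float durations


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds of the detector.

    Defaults are the published operating point: 3-s adaptive-threshold
    segments, 50-ms windows at a 1-ms hop, a 100-ms minimum for vocal events,
    a 50-ms minimum for pauses, and a 150-ms short/long pause boundary.
    """

    segment_duration_s: float = 3.0
    window_ms: float = 50.0
    hop_ms: float = 1.0
    vocal_min_ms: float = 100.0
    pause_min_ms: float = 50.0
    short_long_boundary_ms: float = 150.0
    zcr_zero_tolerance: int = 0

    def __post_init__(self) -> None:
        if not (self.window_ms > self.hop_ms > 0):
            raise ValueError("need window_ms > hop_ms > 0")
        if not (self.vocal_min_ms > self.pause_min_ms > 0):
            raise ValueError("need vocal_min_ms > pause_min_ms > 0")
        if not self.short_long_boundary_ms > self.pause_min_ms:
            raise ValueError("need short_long_boundary_ms > pause_min_ms")
        if self.segment_duration_s * 1000.0 < self.window_ms:
            raise ValueError("segment shorter than one analysis window")


@dataclass(frozen=True)
class FrameSeries:
    """Per-frame RMSE and ZCR on the window/hop grid.

    ``times_s`` are frame-center timestamps; the window *start* convention
    used for region boundaries is available as :attr:`window_starts_s`.
    """

    times_s: np.ndarray
    rmse: np.ndarray
    zcr: np.ndarray
    segment_index: np.ndarray
    window_ms: float
    hop_ms: float

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if not (len(self.rmse) == len(self.zcr) == len(self.segment_index) == n):
            raise ValueError("frame arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def window_starts_s(self) -> np.ndarray:
        return self.times_s - self.window_ms / 2000.0


@dataclass(frozen=True)
class Event:
    """A typed interval: a vocal event or a (short|long) pause."""

    kind: str
    start_s: float
    end_s: float
    pause_subtype: str = NONE

    def __post_init__(self) -> None:
        if self.kind not in (VOCAL, PAUSE):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ValueError("event end must exceed start")
        if self.kind == VOCAL and self.pause_subtype != NONE:
            raise ValueError("vocal events have no pause subtype")

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass(frozen=True)
class EventSequence:
    """Time-ordered, non-overlapping, alternating events of one recording."""

    events: tuple[Event, ...]
    signal_duration_s: float
    config: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        prev = None
        for ev in self.events:
            if prev is not None:
                if ev.start_s < prev.end_s - 1e-9:
                    raise ValueError("events overlap or are unsorted")
                if ev.kind == prev.kind:
                    raise ValueError("adjacent events of the same kind must be merged")
            prev = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def vocals(self) -> list[Event]:
        return [e for e in self.events if e.kind == VOCAL]

    def pauses(self, subtype: str | None = None) -> list[Event]:
        out = [e for e in self.events if e.kind == PAUSE]
        if subtype is not None:
            out = [e for e in out if e.pause_subtype == subtype]
        return out

    def to_dataframe(self, recording_id: str = "recording") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recording_id": recording_id,
                "kind": [e.kind for e in self.events],
                "subtype": [e.pause_subtype for e in self.events],
                "start_s": np.round([e.start_s for e in self.events], 6),
                "end_s": np.round([e.end_s for e in self.events], 6),
                "duration_ms": np.round([e.duration_ms for e in self.events], 3),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_events_csv(path, signal_duration_s: float | None = None,
                    config: DetectionConfig | None = None) -> EventSequence:
    """Read an event table written by :meth:`EventSequence.write_csv`."""
    df = pd.read_csv(path)
    events = tuple(
        Event(kind=row.kind, start_s=row.start_s, end_s=row.end_s,
              pause_subtype=row.subtype)
        for row in df.itertuples()
    )
    dur = signal_duration_s if signal_duration_s is not None else (
        float(df["end_s"].max()) if len(df) else 0.0
    )
    return EventSequence(events=events, signal_duration_s=dur,
                         config=config or DetectionConfig())


# ---------------------------------------------------------------------------
# stage 1: segmentation
# ---------------------------------------------------------------------------

def _segment_bounds(n_samples: int, sample_rate: int, config: DetectionConfig) -> list[tuple[int, int]]:
    """Sample-index bounds of the non-overlapping 3-s segments.

    The trailing remainder is kept as its own segment when it is at least one
    analysis window long, and merged into the previous segment otherwise.
    """
    seg = int(round(config.segment_duration_s * sample_rate))
    win = int(round(config.window_ms / 1000.0 * sample_rate))
    if n_samples < win:
        raise ValueError("signal shorter than one analysis window")
    bounds: list[tuple[int, int]] = []
    n_full = n_samples // seg
    for i in range(n_full):
        bounds.append((i * seg, (i + 1) * seg))
    rem = n_samples - n_full * seg
    if rem > 0:
        if rem >= win or not bounds:
            bounds.append((n_full * seg, n_samples))
        else:
            s, _ = bounds[-1]
            bounds[-1] = (s, n_samples)
    return bounds


def segment_signal(signal: AudioSignal, config: DetectionConfig | None = None
                   ) -> list[tuple[int, AudioSignal]]:
    """Blindly cut ``signal`` into non-overlapping segments (default 3 s)."""
    config = config or DetectionConfig()
    bounds = _segment_bounds(signal.n_samples, signal.sample_rate, config)
    return [
        (i, AudioSignal(samples=signal.samples[a:b], sample_rate=signal.sample_rate))
        for i, (a, b) in enumerate(bounds)
    ]


# ---------------------------------------------------------------------------
# stage 2: short-time features
# ---------------------------------------------------------------------------

def _sliding_rmse_zcr(x: np.ndarray, win: int, hop: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised RMSE and strict-sign-change count for every full window."""
    n = x.size
    if n < win:
        raise ValueError("signal shorter than one analysis window")
    starts = np.arange(0, n - win + 1, hop)
    cs = np.concatenate(([0.0], np.cumsum(x * x)))
    rmse = np.sqrt((cs[starts + win] - cs[starts]) / win)
    # a crossing is a strict sign change between consecutive samples;
    # sign(0) = 0, so transitions into or out of exact zero never count and
    # gated silence has ZCR = 0 by construction
    crossings = (x[:-1] * x[1:] < 0).astype(np.int64)
    cc = np.concatenate(([0], np.cumsum(crossings)))
    zcr = cc[starts + win - 1] - cc[starts]
    return starts, rmse, zcr


def short_time_features(segment: AudioSignal, config: DetectionConfig | None = None,
                        segment_index: int = 0) -> FrameSeries:
    """RMSE and ZCR per 50-ms window at a 1-ms hop, full windows only.

    Frame RMSE is sqrt(mean of squared samples in the window); frame ZCR is
    the number of strict sign changes inside the window (an all-zero window
    has ZCR = 0). No padding is applied: frames exist only where the whole
    window fits inside the segment.
    """
    config = config or DetectionConfig()
    sr = segment.sample_rate
    win = int(round(config.window_ms / 1000.0 * sr))
    hop = max(1, int(round(config.hop_ms / 1000.0 * sr)))
    starts, rmse, zcr = _sliding_rmse_zcr(segment.samples, win, hop)
    times = (starts + win / 2.0) / sr
    return FrameSeries(
        times_s=times, rmse=rmse, zcr=zcr,
        segment_index=np.full(len(starts), segment_index, dtype=np.int64),
        window_ms=config.window_ms, hop_ms=config.hop_ms,
    )


# ---------------------------------------------------------------------------
# stage 3: frame labeling
# ---------------------------------------------------------------------------

def label_frames(frames: FrameSeries, config: DetectionConfig | None = None,
                 mean_rmse: float | None = None) -> np.ndarray:
    """Label every frame silent/nonsilent against the segment's mean RMSE.

    Rule: RMSE above the mean *and* non-zero ZCR -> non-silent; RMSE below the
    mean *and* zero ZCR -> silent. Frames matching neither conjunction
    (including RMSE exactly equal to the mean) are resolved by the ZCR
    criterion alone, since zero ZCR is the signature of gated silence.

    Returns a boolean array, True = non-silent.
    """
    config = config or DetectionConfig()
    if len(frames) == 0:
        raise ValueError("empty frame series")
    mu = float(np.mean(frames.rmse)) if mean_rmse is None else float(mean_rmse)
    zcr_nonzero = frames.zcr > config.zcr_zero_tolerance
    nonsilent_rule = (frames.rmse > mu) & zcr_nonzero
    silent_rule = (frames.rmse < mu) & ~zcr_nonzero
    return np.where(nonsilent_rule, True, np.where(silent_rule, False, zcr_nonzero))


# ---------------------------------------------------------------------------
# stage 4: regions
# ---------------------------------------------------------------------------

def frames_to_regions(labels: Sequence[bool] | np.ndarray, frames: FrameSeries
                      ) -> list[tuple[str, float, float]]:
    """Run-length encode frame labels into contiguous (label, start, end) regions.

    Regions tile the labeled span on the hop grid: a region starts at its
    first frame's window start and ends one hop after its last frame's window
    start. (Detection then refines silent/non-silent boundaries to window
    edges; see :func:`refine_region_boundaries`.)
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(frames):
        raise ValueError("labels and frames are not aligned")
    if len(labels) == 0:
        return []
    starts_s = frames.window_starts_s
    hop_s = frames.hop_ms / 1000.0
    change = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    run_bounds = np.concatenate(([0], change, [len(labels)]))
    regions = []
    for a, b in zip(run_bounds[:-1], run_bounds[1:]):
        label = NONSILENT if labels[a] else SILENT
        regions.append((label, float(starts_s[a]), float(starts_s[b - 1] + hop_s)))
    return regions


def refine_region_boundaries(regions: list[tuple[str, float, float]],
                             config: DetectionConfig,
                             signal_duration_s: float | None = None
                             ) -> list[tuple[str, float, float]]:
    """Move region boundaries from the hop grid to physical window edges.

    A window is silent only when it lies entirely inside silence, so a silent
    run of frames under-covers the true silent stretch by (window - hop) at
    its right edge. Each silent->nonsilent boundary is therefore shifted right
    by (window - hop), and the final region is extended to the end of the
    analyzed span. On clean signals this makes region edges exact. Non-silent
    regions squeezed to non-positive length by the shift (isolated glitches)
    are dropped and their silent neighbours merged.
    """
    if not regions:
        return []
    shift = (config.window_ms - config.hop_ms) / 1000.0
    out = [list(r) for r in regions]
    for left, right in zip(out[:-1], out[1:]):
        if left[0] == SILENT and right[0] == NONSILENT:
            left[2] += shift
            right[1] += shift
    out[-1][2] += shift
    if signal_duration_s is not None:
        out[-1][2] = min(out[-1][2], signal_duration_s)
    # drop regions emptied by the shift, merging same-label neighbours
    merged: list[list] = []
    for label, a, b in out:
        if b - a <= 1e-12:
            continue
        if merged and merged[-1][0] == label:
            merged[-1][2] = b
        else:
            merged.append([label, a, b])
    # re-tile so regions stay contiguous after drops
    for left, right in zip(merged[:-1], merged[1:]):
        right[1] = left[2]
    return [(l, a, b) for l, a, b in merged]


# ---------------------------------------------------------------------------
# stage 5: temporal thresholding
# ---------------------------------------------------------------------------

def classify_events(regions: Iterable[tuple[str, float, float]],
                    config: DetectionConfig | None = None,
                    signal_duration_s: float | None = None) -> EventSequence:
    """Apply the temporal thresholds: regions become vocal/pause events.

    Silent regions >= ``pause_min_ms`` become pauses and non-silent regions
    > ``vocal_min_ms`` become vocal events. Sub-threshold regions are absorbed
    leftward into the running event (a sub-threshold prefix merges rightward
    into the first event); same-kind neighbours are merged.
    """
    config = config or DetectionConfig()
    regions = list(regions)
    if signal_duration_s is None:
        signal_duration_s = regions[-1][2] if regions else 0.0

    events: list[list] = []  # [kind, start, end]
    span_start: float | None = None
    for label, a, b in regions:
        if span_start is None:
            span_start = a
        d_ms = (b - a) * 1000.0
        if label == SILENT:
            kind, qualifies = PAUSE, d_ms >= config.pause_min_ms - _EPS_MS
        else:
            kind, qualifies = VOCAL, d_ms > config.vocal_min_ms + _EPS_MS
        if qualifies:
            if events and events[-1][0] == kind:
                events[-1][2] = b
            else:
                start = span_start if not events else events[-1][2]
                events.append([kind, start, b])
        elif events:
            events[-1][2] = b  # absorb into the running event
        # a sub-threshold prefix is left pending; the first qualifying event
        # starts at span_start and thereby absorbs it rightward

    seq = tuple(Event(kind=k, start_s=a, end_s=b) for k, a, b in events)
    return split_pauses(
        EventSequence(events=seq, signal_duration_s=signal_duration_s, config=config),
        config,
    )


def split_pauses(events: EventSequence, config: DetectionConfig | None = None
                 ) -> EventSequence:
    """Assign each pause its subtype: short (50-150 ms) or long (> 150 ms)."""
    config = config or events.config
    out = []
    for ev in events:
        if ev.kind != PAUSE:
            out.append(replace(ev, pause_subtype=NONE))
            continue
        d = ev.duration_ms
        if d < config.pause_min_ms - _EPS_MS:
            raise ValueError(
                f"pause of {d:.3f} ms below the {config.pause_min_ms}-ms minimum"
            )
        subtype = SHORT if d <= config.short_long_boundary_ms + _EPS_MS else LONG
        out.append(replace(ev, pause_subtype=subtype))
    return EventSequence(events=tuple(out),
                         signal_duration_s=events.signal_duration_s, config=config)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def detect_events(signal: AudioSignal, config: DetectionConfig | None = None
                  ) -> EventSequence:
    """Run the full detector on a preprocessed signal.

    The frame grid is computed once over the whole recording (every position
    where a full window fits inside the signal); the 3-s segmentation defines
    the blocks over which the adaptive mean-RMSE threshold is taken, and
    same-label runs are merged across segment boundaries before temporal
    thresholding, so events straddling a boundary stay whole.
    """
    config = config or DetectionConfig()
    sr = signal.sample_rate
    win = int(round(config.window_ms / 1000.0 * sr))
    hop = max(1, int(round(config.hop_ms / 1000.0 * sr)))
    starts, rmse, zcr = _sliding_rmse_zcr(signal.samples, win, hop)

    bounds = _segment_bounds(signal.n_samples, sr, config)
    seg_index = np.zeros(len(starts), dtype=np.int64)
    for i, (a, _b) in enumerate(bounds):
        seg_index[starts >= a] = i

    frames = FrameSeries(
        times_s=(starts + win / 2.0) / sr, rmse=rmse, zcr=zcr,
        segment_index=seg_index, window_ms=config.window_ms, hop_ms=config.hop_ms,
    )

    labels = np.empty(len(frames), dtype=bool)
    for i in range(len(bounds)):
        in_seg = seg_index == i
        sub = FrameSeries(
            times_s=frames.times_s[in_seg], rmse=rmse[in_seg], zcr=zcr[in_seg],
            segment_index=seg_index[in_seg],
            window_ms=config.window_ms, hop_ms=config.hop_ms,
        )
        labels[in_seg] = label_frames(sub, config)

    regions = frames_to_regions(labels, frames)
    regions = refine_region_boundaries(regions, config, signal.duration_s)
    return classify_events(regions, config, signal_duration_s=signal.duration_s)
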