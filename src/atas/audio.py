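"""Audio container and preprocessing: load, trim, amplitude-normalize.

The downstream event detector assumes that true silence has (near-)zero
amplitude, so the preprocessing contract here is deliberately narrow: get the
recording into a mono, bounded-amplitude representation without resampling
(time-domain parameters are converted to samples per file, which avoids
interpolation artifacts in the zero-crossing rate).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

MIN_SAMPLE_RATE = 8000


class AudioError(ValueError):
    """Invalid audio input (empty, degenerate, or unsupported)."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal: amplitude samples plus sample rate.

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes, nominally in [-1, 1].
    sample_rate : int
        Sampling frequency in Hz; must be >= 8000 (a 50-ms analysis window
        needs at least 400 samples to be meaningful).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise AudioError("empty audio signal")
        if int(self.sample_rate) < MIN_SAMPLE_RATE:
            raise AudioError(
                f"sample rate {self.sample_rate} Hz unsupported; need >= {MIN_SAMPLE_RATE}"
            )
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


def load_audio(path: str | os.PathLike) -> AudioSignal:
    """Read a PCM/float WAV file as a mono, [-1, 1]-scaled :class:`AudioSignal`.

    Multi-channel input is averaged to mono. Integer PCM is rescaled by the
    dtype's full-scale value.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises assorted ValueError subclasses
        raise IOError(f"could not read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise AudioError(f"zero-length audio in {path!r}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
            data = (data.astype(np.float64) - 128.0) / 128.0
        else:
            data = data.astype(np.float64) / float(-info.min)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(samples=data, sample_rate=int(rate))


def save_audio(signal: AudioSignal, path: str | os.PathLike) -> None:
    """Write a signal as a 32-bit float WAV (lossless for our pipeline)."""
    wavfile.write(os.fspath(path), signal.sample_rate, signal.samples.astype(np.float32))


def trim(signal: AudioSignal, start_s: float, end_s: float) -> AudioSignal:
    """Return the sub-signal on [start_s, end_s).

    Used to clip extraneous audio before the first and after the last word of
    the read passage.
    """
    if not (0.0 <= start_s < end_s <= signal.duration_s + 0.5 / signal.sample_rate):
        raise ValueError(
            f"invalid trim bounds [{start_s}, {end_s}) for a "
            f"{signal.duration_s:.3f}-s signal"
        )
    i0 = int(round(start_s * signal.sample_rate))
    i1 = int(round(end_s * signal.sample_rate))
    i1 = min(i1, signal.n_samples)
    return AudioSignal(samples=signal.samples[i0:i1], sample_rate=signal.sample_rate)


def normalize_amplitude(signal: AudioSignal) -> AudioSignal:
    """Peak-normalize: divide by max |sample| so that the output peak is 1.

    Peak (not RMS) normalization is used: the per-segment mean-RMSE threshold
    downstream is scale-invariant, so only a bounded range is required.
    """
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise AudioError("cannot normalize an identically-zero signal")
    return AudioSignal(samples=signal.samples / peak, sample_rate=signal.sample_rate)
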