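"""WAV audio and event-annotation I/O.

All downstream stages consume a mono :class:`AudioSignal` at one canonical
sample rate (8 kHz by default: cough energy lives between roughly 30 Hz and
4 kHz, so an 8 kHz Nyquist suffices).  Multi-channel input is averaged to
mono, matching the single-microphone bedside recorder the pipeline targets.

Event annotations (ground truth or detector output) are stored as a
3-column tab-separated text file ``start_s  end_s  label`` — diff-able and
editor-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical internal sample rate (Hz).
DEFAULT_SAMPLE_RATE = 8000

#: Recognised annotation labels.
EVENT_LABELS = ("cough", "speech", "impact", "noise", "other", "candidate")


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples
        1-D float array, dimensionless amplitude, nominal range [-1, 1].
    sample_rate
        Sampling frequency in Hz (positive integer).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D (mono), got shape {samples.shape}")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds."""
        return len(self) / self.sample_rate

    def normalized(self) -> "AudioSignal":
        """Peak-normalize so that max(|samples|) == 1 (no-op on silence)."""
        peak = float(np.max(np.abs(self.samples))) if len(self) else 0.0
        if peak == 0.0:
            return self
        return AudioSignal(self.samples / peak, self.sample_rate)


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled time interval ``[start_s, end_s)`` within a session."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"require 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "EventAnnotation") -> float:
        """Length in seconds of the intersection with *other* (>= 0)."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))


def read_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF/WAV file as a mono float signal in [-1, 1].

    Integer PCM is rescaled by its type's full scale; float WAV is taken
    as-is.  Multi-channel audio is averaged to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"not a readable WAV file: {path} ({exc})") from exc
    data = np.asarray(data)
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0  # 32768 for int16
        samples = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM, offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples, int(rate))


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write *signal* as 16-bit PCM, clipping to [-1, 1] before quantization."""
    samples = signal.samples
    if not np.all(np.isfinite(samples)):
        raise ValueError("cannot write non-finite samples")
    clipped = np.clip(samples, -1.0, 1.0)
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Band-limited resampling to *target_rate* Hz.

    Output length is ``round(len * target / source)``; duration in seconds
    is preserved to within one output sample.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.sample_rate or len(signal) == 0:
        return AudioSignal(signal.samples.copy(), target_rate if len(signal) == 0 else signal.sample_rate)
    ratio = Fraction(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    n_target = int(round(len(signal) * target_rate / signal.sample_rate))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)))
    return AudioSignal(out, int(target_rate))


def load_audio(path: str | Path, sample_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Read a WAV file and resample it to the canonical pipeline rate."""
    return resample(read_wav(path), sample_rate)


def write_annotations(events: Iterable[EventAnnotation], path: str | Path) -> None:
    """Write events as a TSV of ``start_s<TAB>end_s<TAB>label`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for ev in events:
            fh.write(f"{ev.start_s:.4f}\t{ev.end_s:.4f}\t{ev.label}\n")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation TSV written by :func:`write_annotations`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such annotation file: {path}")
    events: list[EventAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("start_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            events.append(EventAnnotation(float(parts[0]), float(parts[1]), parts[2]))
    return events
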