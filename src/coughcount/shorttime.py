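"""Framing and the three short-time descriptors.

Every frame-level stage of the pipeline shares one :class:`FrameGrid`
(default 25 ms frames, 10 ms hop at 8 kHz).  Three classic descriptors are
computed per frame:

* **mean amplitude** — mean of |x|, a loudness proxy.  (Averaging the raw
  signed samples would be ~0 for any zero-mean audio, so the absolute
  value is taken.)
* **short-time zero-crossing rate (ZCR)** — number of sign changes within
  the frame, ``(1/2) * sum |sgn x(m) - sgn x(m-1)|`` with ``sgn(0) := +1``
  so exact zeros never double-count; a proxy for high-frequency content.
* **short-time energy** — sum of squared windowed samples,
  ``sum (x(m) w(m))^2``; with the rectangular window this is simply
  ``sum x(m)^2``.  A proxy for burst intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .audio_io import AudioSignal

WindowKind = Literal["rectangular", "hamming"]


@dataclass(frozen=True)
class FrameGrid:
    """Framing parameters governing all short-time analysis.

    ``frame_len`` and ``hop`` are in samples; frame k covers the half-open
    sample interval ``[k*hop, k*hop + frame_len)``.  An incomplete final
    frame is dropped (no padding).
    """

    frame_len: int = 200
    hop: int = 80
    window: WindowKind = "rectangular"

    def __post_init__(self) -> None:
        if not (1 <= self.hop <= self.frame_len):
            raise ValueError(
                f"require 1 <= hop <= frame_len, got hop={self.hop}, "
                f"frame_len={self.frame_len}"
            )
        if self.window not in ("rectangular", "hamming"):
            raise ValueError(f"unknown window kind {self.window!r}")

    @classmethod
    def from_ms(
        cls, sample_rate: int, frame_ms: float = 25.0, hop_ms: float = 10.0,
        window: WindowKind = "rectangular",
    ) -> "FrameGrid":
        return cls(
            frame_len=int(round(frame_ms * sample_rate / 1000.0)),
            hop=int(round(hop_ms * sample_rate / 1000.0)),
            window=window,
        )

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.frame_len:
            return 0
        return (n_samples - self.frame_len) // self.hop + 1

    def frame_start(self, frame_index: int) -> int:
        """First sample covered by frame *frame_index*."""
        return frame_index * self.hop

    def window_values(self) -> np.ndarray:
        if self.window == "hamming":
            return np.hamming(self.frame_len)
        return np.ones(self.frame_len)


@dataclass(frozen=True)
class ShortTimeSeries:
    """A per-frame descriptor sequence tied to its frame grid."""

    values: np.ndarray
    grid: FrameGrid

    def __len__(self) -> int:
        return len(self.values)

    def frame_start(self, frame_index: int) -> int:
        return self.grid.frame_start(frame_index)


def frame_signal(signal: AudioSignal | np.ndarray, grid: FrameGrid) -> np.ndarray:
    """Slice a signal into overlapping frames; shape (n_frames, frame_len).

    Degenerate input (shorter than one frame) yields an empty array.
    """
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, dtype=np.float64)
    n = grid.n_frames(len(x))
    if n == 0:
        return np.empty((0, grid.frame_len))
    idx = grid.hop * np.arange(n)[:, None] + np.arange(grid.frame_len)[None, :]
    return x[idx]


def mean_amplitude(segment: np.ndarray) -> float:
    """Mean of |x| over the samples — the loudness of a stretch of signal."""
    x = np.asarray(segment, dtype=np.float64)
    if x.size == 0:
        raise ValueError("mean_amplitude of an empty segment is undefined")
    return float(np.mean(np.abs(x)))


def _sgn(x: np.ndarray) -> np.ndarray:
    # sgn in {-1, +1} with sgn(0) := +1 (deterministic tie-break)
    return np.where(x >= 0, 1.0, -1.0)


def short_time_zcr(frame: np.ndarray) -> int:
    """Zero crossings in one frame: (1/2) sum |sgn x(m) - sgn x(m-1)|."""
    x = np.asarray(frame, dtype=np.float64)
    if x.size < 2:
        return 0
    s = _sgn(x)
    return int(round(0.5 * np.sum(np.abs(s[1:] - s[:-1]))))


def short_time_energy(frame: np.ndarray, window: WindowKind = "rectangular") -> float:
    """Energy of one frame: sum of squared windowed samples."""
    x = np.asarray(frame, dtype=np.float64)
    if x.size == 0:
        raise ValueError("short_time_energy of an empty frame is undefined")
    if window == "hamming":
        x = x * np.hamming(x.size)
    elif window != "rectangular":
        raise ValueError(f"unknown window kind {window!r}")
    return float(np.sum(x**2))


def series_over_signal(
    signal: AudioSignal | np.ndarray, grid: FrameGrid, which: Literal["energy", "zcr"]
) -> ShortTimeSeries:
    """Per-frame energy or ZCR over the whole signal."""
    frames = frame_signal(signal, grid)
    if which == "energy":
        w = grid.window_values()
        values = np.sum((frames * w) ** 2, axis=1)
    elif which == "zcr":
        if frames.shape[0] == 0:
            values = np.empty(0)
        else:
            s = _sgn(frames)
            values = 0.5 * np.sum(np.abs(np.diff(s, axis=1)), axis=1)
    else:
        raise ValueError(f"unknown descriptor {which!r}")
    return ShortTimeSeries(values=np.asarray(values, dtype=np.float64), grid=grid)
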