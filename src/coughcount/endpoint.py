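"""Coarse 20-s chunking and dual-threshold endpoint detection.

Long bedside recordings are first cut into fixed 20-s chunks (the last one
zero-padded) so every later stage works on bounded input.  Within a chunk,
candidate cough segments are found by the classical two-stage
dual-threshold detector over the per-frame short-time energy and
zero-crossing-rate series:

1. a segment is *seeded* wherever frame energy exceeds the high threshold;
2. it is *extended* over the surrounding run of frames whose energy stays
   above the low threshold, then outward frame-by-frame while the ZCR
   stays above its threshold (bounded by ``zcr_extend_s``, since ZCR is
   amplitude-independent and would otherwise extend through any wideband
   noise floor);
3. segments separated by less than a short silence gap are merged, so the
   burst onset and the decaying body of one cough are never split.

Cough-specific constraints are then applied: a duration gate (a cough is a
short explosive event) and a minimum peak frame energy (suppressing weak
tails such as post-cough wheezes that would double-count).

Energy thresholds default to multiples of the chunk's median frame energy,
adapting to recorder gain differences; the zero-padded region of the final
chunk is excluded from the median so it cannot bias the thresholds down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioSignal
from .shorttime import FrameGrid, series_over_signal

#: Chunk duration in seconds used by the coarse segmentation.
CHUNK_SECONDS = 20.0


@dataclass(frozen=True)
class Chunk:
    """One fixed-duration piece of a session; only the last may be padded."""

    signal: AudioSignal
    index: int
    pad_samples: int

    def __post_init__(self) -> None:
        expected = int(round(CHUNK_SECONDS * self.signal.sample_rate))
        if len(self.signal) != expected:
            raise ValueError(
                f"chunk must be exactly {CHUNK_SECONDS:g} s "
                f"({expected} samples), got {len(self.signal)}"
            )
        if not (0 <= self.pad_samples < expected):
            raise ValueError(f"pad_samples out of range: {self.pad_samples}")

    @property
    def n_valid(self) -> int:
        """Number of samples that come from the original signal."""
        return len(self.signal) - self.pad_samples


@dataclass(frozen=True)
class Segment:
    """A candidate cough: half-open sample interval within one chunk."""

    start: int
    end: int
    chunk_index: int
    max_energy: float
    sample_rate: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.sample_rate

    @property
    def session_start_s(self) -> float:
        """Start time in seconds from the beginning of the session."""
        return self.chunk_index * CHUNK_SECONDS + self.start / self.sample_rate

    @property
    def session_end_s(self) -> float:
        return self.chunk_index * CHUNK_SECONDS + self.end / self.sample_rate


@dataclass(frozen=True)
class DetectorThresholds:
    """Resolved (absolute) thresholds for one chunk.

    ``energy_high`` seeds segments, ``energy_low`` extends them,
    ``zcr_low`` (crossings/frame) drives the bounded outward ZCR
    extension.  ``min_duration_s``/``max_duration_s`` and
    ``min_max_energy`` are the cough-specific gates.
    """

    energy_high: float
    energy_low: float
    zcr_low: float
    min_duration_s: float = 0.15
    max_duration_s: float = 1.2
    min_max_energy: float = 0.0
    max_silence_gap_s: float = 0.12
    zcr_extend_s: float = 0.10

    def __post_init__(self) -> None:
        if self.energy_low > self.energy_high:
            raise ValueError("energy_low must not exceed energy_high")
        if not (self.min_duration_s < self.max_duration_s):
            raise ValueError("min_duration_s must be < max_duration_s")


@dataclass(frozen=True)
class EndpointConfig:
    """Relative detector configuration; resolved per chunk against the
    median frame energy (adapts to recorder gain)."""

    energy_high_scale: float = 8.0
    energy_low_scale: float = 2.0
    zcr_low: float = 10.0
    min_dur_s: float = 0.15
    max_dur_s: float = 1.2
    min_max_energy_scale: float = 15.0
    merge_gap_s: float = 0.12
    zcr_extend_s: float = 0.10
    #: The effective ZCR threshold is max(zcr_low, zcr_floor_scale * median
    #: frame ZCR of the chunk): the crossing rate of a noise floor depends on
    #: its bandwidth, not its amplitude, so a fixed count alone would let the
    #: extension run through any wideband floor.
    zcr_floor_scale: float = 1.2


def coarse_segment(signal: AudioSignal) -> list[Chunk]:
    """Cut a session into consecutive 20-s chunks, zero-padding the last."""
    n = len(signal)
    if n == 0:
        return []
    chunk_len = int(round(CHUNK_SECONDS * signal.sample_rate))
    n_chunks = -(-n // chunk_len)  # ceil
    chunks: list[Chunk] = []
    for i in range(n_chunks):
        piece = signal.samples[i * chunk_len : (i + 1) * chunk_len]
        pad = chunk_len - len(piece)
        if pad:
            piece = np.pad(piece, (0, pad))
        chunks.append(Chunk(AudioSignal(piece, signal.sample_rate), i, pad))
    return chunks


def resolve_thresholds(chunk: Chunk, grid: FrameGrid, cfg: EndpointConfig = EndpointConfig()) -> DetectorThresholds:
    """Turn relative threshold scales into absolute per-chunk thresholds.

    The reference level is the median frame energy over the un-padded part
    of the chunk (a robust noise-floor estimate: coughs are sparse).
    """
    energy = series_over_signal(chunk.signal, grid, "energy").values
    zcr = series_over_signal(chunk.signal, grid, "zcr").values
    n_valid_frames = grid.n_frames(chunk.n_valid)
    if n_valid_frames < 1:
        n_valid_frames = len(energy)
    ref_e = energy[:n_valid_frames]
    ref_z = zcr[:n_valid_frames]
    median_e = float(np.median(ref_e)) if len(ref_e) else 0.0
    median_z = float(np.median(ref_z)) if len(ref_z) else 0.0
    return DetectorThresholds(
        energy_high=cfg.energy_high_scale * median_e,
        energy_low=cfg.energy_low_scale * median_e,
        zcr_low=max(cfg.zcr_low, cfg.zcr_floor_scale * median_z),
        min_duration_s=cfg.min_dur_s,
        max_duration_s=cfg.max_dur_s,
        min_max_energy=cfg.min_max_energy_scale * median_e,
        max_silence_gap_s=cfg.merge_gap_s,
        zcr_extend_s=cfg.zcr_extend_s,
    )


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (first, last) index pairs."""
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(0, len(edges), 2)]


def dual_threshold_detect(
    chunk: Chunk, grid: FrameGrid, th: DetectorThresholds
) -> list[Segment]:
    """Two-stage energy/ZCR activity detection over one chunk.

    Returns chronologically ordered, non-overlapping candidate segments as
    half-open sample intervals.  No activity yields an empty list.
    """
    energy = series_over_signal(chunk.signal, grid, "energy").values
    zcr = series_over_signal(chunk.signal, grid, "zcr").values
    n_frames = len(energy)
    if n_frames == 0:
        return []

    seeds = energy > th.energy_high
    active = energy > th.energy_low
    max_ext = int(round(th.zcr_extend_s * chunk.signal.sample_rate / grid.hop))

    frame_runs: list[tuple[int, int]] = []
    for f0, f1 in _runs_of(active):
        if not seeds[f0 : f1 + 1].any():
            continue
        lo = f0
        while lo > 0 and f0 - (lo - 1) <= max_ext and zcr[lo - 1] > th.zcr_low:
            lo -= 1
        hi = f1
        while hi < n_frames - 1 and (hi + 1) - f1 <= max_ext and zcr[hi + 1] > th.zcr_low:
            hi += 1
        frame_runs.append((lo, hi))

    # merge runs separated by less than the silence gap
    gap_frames = int(round(th.max_silence_gap_s * chunk.signal.sample_rate / grid.hop))
    merged: list[tuple[int, int]] = []
    for run in frame_runs:
        if merged and run[0] - merged[-1][1] <= gap_frames:
            merged[-1] = (merged[-1][0], max(merged[-1][1], run[1]))
        else:
            merged.append(run)

    chunk_len = len(chunk.signal)
    segments: list[Segment] = []
    for f0, f1 in merged:
        start = grid.frame_start(f0)
        end = min(grid.frame_start(f1) + grid.frame_len, chunk_len)
        if segments and start < segments[-1].end:  # guard against frame overlap
            start = segments[-1].end
            if start >= end:
                continue
        segments.append(
            Segment(
                start=start,
                end=end,
                chunk_index=chunk.index,
                max_energy=float(np.max(energy[f0 : f1 + 1])),
                sample_rate=chunk.signal.sample_rate,
            )
        )
    return segments


def apply_cough_constraints(
    segments: list[Segment], th: DetectorThresholds
) -> list[Segment]:
    """Keep segments that look like coughs: pure filter, order preserved.

    A segment survives iff its duration lies in
    ``[min_duration_s, max_duration_s]`` and its peak frame energy is at
    least ``min_max_energy`` (the explosive-onset requirement that
    suppresses weak cough tails and background swells).
    """
    return [
        s
        for s in segments
        if th.min_duration_s <= s.duration_s <= th.max_duration_s
        and s.max_energy >= th.min_max_energy
    ]


def rejection_reason(segment: Segment, th: DetectorThresholds) -> str | None:
    """Why :func:`apply_cough_constraints` would drop *segment* (None = kept)."""
    if not (th.min_duration_s <= segment.duration_s <= th.max_duration_s):
        return "duration"
    if segment.max_energy < th.min_max_energy:
        return "max_energy"
    return None
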