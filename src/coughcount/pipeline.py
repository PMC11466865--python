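"""End-to-end session processing and per-minute cough-frequency counting.

The flow: denoise -> 20-s coarse chunks -> dual-threshold endpoint
detection -> cough-shape constraints -> 17-dim segment features -> SVM
label -> per-chunk counts.  Since each chunk is 20 s, the cough frequency
of minute j is the sum of three consecutive chunk counts,

    F_C(j) = N_(3j+1) + N_(3j+2) + N_(3j+3),

and a trailing partial minute (1-2 chunks) is reported separately, never
zero-padded into a fake minute.  Every candidate segment ends up in
exactly one of accepted/rejected, with the rejection stage recorded
(duration gate, peak-energy gate, or classifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, EventAnnotation
from .cepstral import build_filterbank, segment_features
from .classify import POSITIVE_LABEL, CoughClassifier
from .config import RunConfig
from .denoise import wavelet_denoise
from .endpoint import (
    CHUNK_SECONDS,
    Segment,
    apply_cough_constraints,
    coarse_segment,
    dual_threshold_detect,
    rejection_reason,
    resolve_thresholds,
)
from .synthgen import SessionTruth

logger = logging.getLogger(__name__)

#: 20-s chunks per minute (Eq: three chunks sum to one minute's count).
CHUNKS_PER_MINUTE = 3


@dataclass(frozen=True)
class SegmentRecord:
    """One candidate segment and its fate."""

    start_s: float
    end_s: float
    chunk_index: int
    label: str           # "Cough" / "Noise" for classified, "rejected" stages keep label "Noise"
    reason: str | None   # None if accepted, else duration | max_energy | classifier


@dataclass(frozen=True)
class SessionResult:
    """Outcome of processing one session."""

    per_chunk_counts: list[int]
    per_minute_fc: list[int]
    partial_minute: int | None
    partial_n_chunks: int
    accepted_segments: list[SegmentRecord]
    rejected_segments: list[SegmentRecord]
    provenance: dict

    @property
    def total_coughs(self) -> int:
        return len(self.accepted_segments)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {
            "per_chunk_counts": self.per_chunk_counts,
            "per_minute_fc": self.per_minute_fc,
            "partial_minute": self.partial_minute,
            "partial_n_chunks": self.partial_n_chunks,
            "accepted_segments": [asdict(s) for s in self.accepted_segments],
            "rejected_segments": [asdict(s) for s in self.rejected_segments],
            "provenance": self.provenance,
        }


def count_per_minute(per_chunk_counts: list[int]) -> tuple[list[int], int | None, int]:
    """Sum consecutive triples of 20-s chunk counts into minute counts.

    Returns ``(minutes, partial, partial_n_chunks)``: *partial* is the
    summed count of a trailing 1- or 2-chunk remainder (None if the
    session divides into whole minutes).
    """
    counts = [int(c) for c in per_chunk_counts]
    if any(c < 0 for c in counts):
        raise ValueError("chunk counts must be non-negative")
    n_full = len(counts) // CHUNKS_PER_MINUTE
    minutes = [
        sum(counts[i * CHUNKS_PER_MINUTE : (i + 1) * CHUNKS_PER_MINUTE])
        for i in range(n_full)
    ]
    rest = counts[n_full * CHUNKS_PER_MINUTE :]
    partial = sum(rest) if rest else None
    return minutes, partial, len(rest)


def process_session(
    signal: AudioSignal, model: CoughClassifier, config: RunConfig = RunConfig()
) -> SessionResult:
    """Run the full counting pipeline over one session recording."""
    if config.sample_rate != signal.sample_rate:
        raise ValueError(
            f"signal rate {signal.sample_rate} != configured rate "
            f"{config.sample_rate}; resample on load"
        )
    if config.denoise_enabled and len(signal) >= 2**config.denoise.levels:
        signal = wavelet_denoise(signal, config.denoise)

    grid = config.frames.grid(config.sample_rate)
    bank = build_filterbank(
        n_filters=config.filterbank.n_filters,
        fft_size=config.filterbank.fft_size,
        sample_rate=config.sample_rate,
        f_low=config.filterbank.f_low,
        f_high=config.filterbank.f_high,
    )

    accepted: list[SegmentRecord] = []
    rejected: list[SegmentRecord] = []
    chunks = coarse_segment(signal)
    per_chunk_counts: list[int] = []
    for chunk in chunks:
        th = resolve_thresholds(chunk, grid, config.endpoint)
        candidates = dual_threshold_detect(chunk, grid, th)
        survivors: list[Segment] = []
        for seg in candidates:
            reason = rejection_reason(seg, th)
            if reason is None:
                survivors.append(seg)
            else:
                rejected.append(SegmentRecord(
                    seg.session_start_s, seg.session_end_s, chunk.index,
                    "Noise", reason,
                ))
        assert survivors == apply_cough_constraints(candidates, th)

        n_coughs = 0
        if survivors:
            feats = np.vstack([
                segment_features(
                    chunk.signal.samples[s.start : s.end], grid, bank, config.cepstral
                ).values
                for s in survivors
            ])
            labels = model.predict(feats)
            for seg, label in zip(survivors, labels):
                rec = SegmentRecord(
                    seg.session_start_s, seg.session_end_s, chunk.index,
                    str(label), None if label == POSITIVE_LABEL else "classifier",
                )
                if label == POSITIVE_LABEL:
                    accepted.append(rec)
                    n_coughs += 1
                else:
                    rejected.append(rec)
        per_chunk_counts.append(n_coughs)
        logger.info(
            "chunk %d: %d candidates, %d after constraints, %d coughs",
            chunk.index, len(candidates), len(survivors), n_coughs,
        )

    minutes, partial, n_rest = count_per_minute(per_chunk_counts)
    return SessionResult(
        per_chunk_counts=per_chunk_counts,
        per_minute_fc=minutes,
        partial_minute=partial,
        partial_n_chunks=n_rest,
        accepted_segments=accepted,
        rejected_segments=rejected,
        provenance={"config_hash": config.config_hash(), "seed": config.seed},
    )


def candidate_dataset(
    sessions: list[tuple[AudioSignal, SessionTruth]],
    config: RunConfig = RunConfig(),
    min_overlap: float = 0.5,
):
    """Training data from annotated sessions, the way the deployed
    pipeline will see it: run denoising, chunking, endpoint detection and
    the cough constraints, then label each surviving candidate ``Cough``
    if it overlaps a true cough by at least ``min_overlap`` of the event's
    duration, else ``Noise``.

    Returns a :class:`~coughcount.classify.LabeledDataset`.
    """
    from .classify import LabeledDataset

    grid = config.frames.grid(config.sample_rate)
    bank = build_filterbank(
        n_filters=config.filterbank.n_filters,
        fft_size=config.filterbank.fft_size,
        sample_rate=config.sample_rate,
        f_low=config.filterbank.f_low,
        f_high=config.filterbank.f_high,
    )
    rows, labels = [], []
    for signal, truth in sessions:
        if config.denoise_enabled and len(signal) >= 2**config.denoise.levels:
            signal = wavelet_denoise(signal, config.denoise)
        coughs = truth.cough_events()
        for chunk in coarse_segment(signal):
            th = resolve_thresholds(chunk, grid, config.endpoint)
            candidates = apply_cough_constraints(
                dual_threshold_detect(chunk, grid, th), th
            )
            for seg in candidates:
                rows.append(segment_features(
                    chunk.signal.samples[seg.start : seg.end], grid, bank,
                    config.cepstral,
                ).values)
                is_cough = any(
                    min(ev.end_s, seg.session_end_s) - max(ev.start_s, seg.session_start_s)
                    >= min_overlap * ev.duration_s
                    for ev in coughs
                )
                labels.append(POSITIVE_LABEL if is_cough else "Noise")
    if not rows:
        raise ValueError("no candidate segments were extracted from the sessions")
    return LabeledDataset(np.vstack(rows), np.asarray(labels))


def accepted_annotations(result: SessionResult) -> list[EventAnnotation]:
    """Accepted segments as session-time annotations (label 'cough')."""
    return [
        EventAnnotation(r.start_s, r.end_s, "cough") for r in result.accepted_segments
    ]


@dataclass(frozen=True)
class CountingErrorReport:
    """Per-minute counting error and event-level matching of one session."""

    per_minute_abs_error: list[int]
    mean_abs_error: float
    partial_abs_error: int | None
    n_true_coughs: int
    n_matched: int
    n_missed: int
    n_false_alarms: int


def truth_chunk_counts(truth: SessionTruth) -> list[int]:
    """True cough count per 20-s chunk (events assigned by their midpoint)."""
    n_chunks = int(np.ceil(truth.session_duration_s / CHUNK_SECONDS))
    counts = [0] * max(n_chunks, 1)
    for ev in truth.cough_events():
        mid = 0.5 * (ev.start_s + ev.end_s)
        counts[min(int(mid // CHUNK_SECONDS), n_chunks - 1)] += 1
    return counts


def score_counts(
    result: SessionResult, truth: SessionTruth, min_overlap: float = 0.5
) -> CountingErrorReport:
    """Compare a session result against ground truth.

    Per-minute absolute counting error compares F_C with the true cough
    count of the same three chunks.  Event matching greedily pairs each
    true cough with an accepted segment overlapping it by at least
    ``min_overlap`` of the true event's duration.
    """
    true_minutes, true_partial, _ = count_per_minute(truth_chunk_counts(truth))
    n = min(len(true_minutes), len(result.per_minute_fc))
    per_min_err = [
        abs(result.per_minute_fc[i] - true_minutes[i]) for i in range(n)
    ]
    mean_err = float(np.mean(per_min_err)) if per_min_err else 0.0
    partial_err = None
    if result.partial_minute is not None and true_partial is not None:
        partial_err = abs(result.partial_minute - true_partial)

    coughs = truth.cough_events()
    detections = list(result.accepted_segments)
    used: set[int] = set()
    matched = 0
    for ev in coughs:
        best, best_ov = None, 0.0
        for j, det in enumerate(detections):
            if j in used:
                continue
            ov = max(0.0, min(ev.end_s, det.end_s) - max(ev.start_s, det.start_s))
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None and best_ov >= min_overlap * ev.duration_s:
            used.add(best)
            matched += 1
    return CountingErrorReport(
        per_minute_abs_error=per_min_err,
        mean_abs_error=mean_err,
        partial_abs_error=partial_err,
        n_true_coughs=len(coughs),
        n_matched=matched,
        n_missed=len(coughs) - matched,
        n_false_alarms=len(detections) - matched,
    )
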