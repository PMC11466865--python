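"""Synthetic annotated audio sessions for training, testing and benchmarks.

No redistributable bedside cough corpus exists, so sessions are emulated
from the acoustic signatures the detector and classifier actually sense:

* **cough** — a band-limited (30 Hz - 4 kHz) noise burst with the
  three-phase envelope of a real cough: a short explosive onset that
  reaches peak energy quickly, a longer decaying body, and (with some
  probability, not every time) a weaker second burst from vocal-fold
  vibration just before the end.
* **speech** — a low-amplitude sum of harmonics over a fundamental with
  slow amplitude modulation: much lower energy than a cough.
* **impact** — a one-sided low-frequency damped oscillation (an object
  hitting a surface): cough-like energy but near-zero zero-crossing rate.
* **background** — slowly ramping low-amplitude wideband noise.

Events are placed uniformly at random without overlap into a session over
a wideband noise floor whose level is set by the requested session SNR
(defined against the mean event power).  Everything is reproducible from
a single seed, and every event is recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import DEFAULT_SAMPLE_RATE, AudioSignal, EventAnnotation

DISTRACTOR_KINDS = ("speech", "impact", "background")

#: Default distractor durations in seconds.
_DISTRACTOR_DUR_S = {"speech": 1.5, "impact": 0.3, "background": 2.0}

#: Annotation label used for each distractor kind.
_DISTRACTOR_LABEL = {"speech": "speech", "impact": "impact", "background": "noise"}

#: Default session signal-to-noise ratio in dB (a quiet bedside room:
#: events well above the floor, but the floor clearly audible).
DEFAULT_SESSION_SNR_DB = 15.0


@dataclass(frozen=True)
class CoughEventParams:
    """Shape of a synthetic cough: three phases with ordered peak gains."""

    initial_dur_s: float = 0.08
    middle_dur_s: float = 0.35
    ending_dur_s: float = 0.12
    initial_gain: float = 1.0
    middle_gain: float = 0.8
    ending_gain: float = 0.45
    ending_prob: float = 0.5
    ending_gap_s: float = 0.04
    middle_decay_to: float = 0.35
    band: tuple[float, float] = (30.0, 4000.0)

    def __post_init__(self) -> None:
        if min(self.initial_dur_s, self.middle_dur_s, self.ending_dur_s) <= 0:
            raise ValueError("phase durations must be positive")
        if not (0.0 <= self.ending_prob <= 1.0):
            raise ValueError("ending_prob must be a probability")


@dataclass(frozen=True)
class SessionTruth:
    """Ground truth of a generated session."""

    events: tuple[EventAnnotation, ...]
    session_duration_s: float
    seed: int
    generator_params: dict

    def cough_events(self) -> list[EventAnnotation]:
        return [e for e in self.events if e.label == "cough"]


def _band_noise(n: int, sample_rate: int, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited to *band* (clipped below Nyquist)."""
    x = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    lo = max(band[0], 1.0) / nyq
    hi = min(band[1], 0.98 * nyq) / nyq
    sos = butter(4, [lo, hi], btype="bandpass", output="sos")
    x = sosfilt(sos, x)
    rms = float(np.sqrt(np.mean(x**2)))
    return x / rms if rms > 0 else x


def generate_cough(
    params: CoughEventParams = CoughEventParams(),
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One synthetic cough event (dimensionless amplitude, peak ~ initial_gain).

    The frame-energy profile rises to its maximum within the onset and
    then decays; with probability ``ending_prob`` a weaker second burst
    follows a short gap before the end.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sr = sample_rate

    n_init = max(int(round(params.initial_dur_s * sr)), 2)
    n_mid = max(int(round(params.middle_dur_s * sr)), 2)
    attack = max(n_init // 4, 1)
    env_init = np.concatenate([
        np.linspace(0.15, 1.0, attack), np.full(n_init - attack, 1.0)
    ]) * params.initial_gain
    # exponential decay of the body down to middle_decay_to of its start
    decay = np.exp(np.linspace(0.0, np.log(params.middle_decay_to), n_mid))
    env_mid = params.middle_gain * decay

    pieces = [env_init, env_mid]
    if rng.random() < params.ending_prob:
        n_gap = int(round(params.ending_gap_s * sr))
        n_end = max(int(round(params.ending_dur_s * sr)), 2)
        bump = np.sin(np.linspace(0.0, np.pi, n_end)) ** 0.5
        pieces += [np.full(n_gap, 0.02), params.ending_gain * bump]
    envelope = np.concatenate(pieces)

    return _band_noise(len(envelope), sr, params.band, rng) * envelope


def generate_distractor(
    kind: str,
    duration_s: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One non-cough sound event of the given *kind*."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sr = sample_rate
    n = int(round(duration_s * sr))
    t = np.arange(n) / sr

    if kind == "speech":
        f0 = rng.uniform(120.0, 220.0)
        x = np.zeros(n)
        for h in range(1, 7):  # harmonic stack with 1/h rolloff
            x += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
        am = 0.55 + 0.45 * np.sin(2 * np.pi * rng.uniform(2.5, 5.0) * t
                                  + rng.uniform(0, 2 * np.pi))
        x *= am
        rms = float(np.sqrt(np.mean(x**2)))
        return 0.18 * x / rms if rms > 0 else x
    if kind == "impact":
        f = rng.uniform(30.0, 60.0)
        tau = rng.uniform(0.05, 0.10)
        # strictly positive waveform: high energy, essentially no crossings
        x = np.exp(-t / tau) * (0.55 + 0.45 * np.sin(2 * np.pi * f * t))
        return 1.2 * x
    if kind == "background":
        x = _band_noise(n, sr, (30.0, 4000.0), rng)
        ramp = np.linspace(0.25, 1.0, n)
        return 0.05 * x * ramp
    raise ValueError(f"unknown distractor kind {kind!r}; "
                     f"expected one of {DISTRACTOR_KINDS}")


def _place_events(
    durations: list[float], session_s: float, rng: np.random.Generator,
    min_gap_s: float = 0.3, max_tries: int = 2000,
) -> list[float]:
    """Uniform non-overlapping start times; raises if they cannot fit."""
    if sum(durations) + min_gap_s * len(durations) > session_s:
        raise ValueError(
            f"cannot place {len(durations)} events totalling "
            f"{sum(durations):.1f} s in a {session_s:.1f} s session"
        )
    placed: list[tuple[float, float]] = []
    starts: list[float] = []
    for dur in durations:
        for _ in range(max_tries):
            start = rng.uniform(0.0, session_s - dur)
            ok = all(start + dur + min_gap_s <= s or start >= e + min_gap_s
                     for s, e in placed)
            if ok:
                placed.append((start, start + dur))
                starts.append(start)
                break
        else:
            raise ValueError(
                f"failed to place an event of {dur:.2f} s after {max_tries} tries"
            )
    return starts


def generate_session(
    n_coughs: int,
    n_distractors: Mapping[str, int] | None = None,
    duration_s: float = 60.0,
    snr_db: float = DEFAULT_SESSION_SNR_DB,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    cough_params: CoughEventParams = CoughEventParams(),
) -> tuple[AudioSignal, SessionTruth]:
    """A full annotated session: events over a noise floor.

    The floor is wideband noise scaled so that the ratio of mean event
    power to floor power equals ``snr_db``.  Identical seeds give
    bit-identical output.
    """
    if n_coughs < 0 or duration_s <= 0:
        raise ValueError("n_coughs must be >= 0 and duration_s > 0")
    n_distractors = dict(n_distractors or {})
    for kind in n_distractors:
        if kind not in DISTRACTOR_KINDS:
            raise ValueError(f"unknown distractor kind {kind!r}")

    rng = np.random.default_rng(seed)
    waveforms: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(n_coughs):
        waveforms.append(generate_cough(cough_params, sample_rate, rng))
        labels.append("cough")
    for kind in DISTRACTOR_KINDS:
        for _ in range(n_distractors.get(kind, 0)):
            waveforms.append(
                generate_distractor(kind, _DISTRACTOR_DUR_S[kind], sample_rate, rng)
            )
            labels.append(_DISTRACTOR_LABEL[kind])

    durations = [len(w) / sample_rate for w in waveforms]
    starts = _place_events(durations, duration_s, rng) if waveforms else []

    n = int(round(duration_s * sample_rate))
    floor = _band_noise(n, sample_rate, (30.0, 4000.0), rng)
    if waveforms:
        mean_event_power = float(np.mean([np.mean(w**2) for w in waveforms]))
        floor_rms = np.sqrt(mean_event_power) * 10.0 ** (-snr_db / 20.0)
    else:
        floor_rms = 0.01
    mix = floor * floor_rms
    events: list[EventAnnotation] = []
    for w, label, start in zip(waveforms, labels, starts):
        i0 = int(round(start * sample_rate))
        i1 = min(i0 + len(w), n)
        mix[i0:i1] += w[: i1 - i0]
        events.append(EventAnnotation(i0 / sample_rate, i1 / sample_rate, label))

    peak = float(np.max(np.abs(mix))) if n else 0.0
    if peak > 1.0:  # keep within WAV range without changing the SNR
        mix /= peak

    events.sort(key=lambda e: e.start_s)
    truth = SessionTruth(
        events=tuple(events),
        session_duration_s=duration_s,
        seed=seed,
        generator_params={
            "n_coughs": n_coughs,
            "n_distractors": n_distractors,
            "snr_db": snr_db,
            "sample_rate": sample_rate,
            "cough_params": asdict(cough_params),
        },
    )
    return AudioSignal(mix, sample_rate), truth


def benchmark_dataset(
    n_segments: int = 400,
    seed: int = 0,
    use_lpcc: bool = False,
    snr_db: float = DEFAULT_SESSION_SNR_DB,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
):
    """Labelled feature dataset of isolated generated events.

    Half the segments are coughs; the rest cycle through the three
    distractor kinds.  Each event is embedded in a noise floor at the
    session SNR before feature extraction, mirroring what the endpoint
    detector hands the classifier.

    Returns a :class:`~coughcount.classify.LabeledDataset` whose columns
    follow :func:`~coughcount.cepstral.feature_names`.
    """
    from .cepstral import CepstralConfig, build_filterbank, segment_features
    from .classify import LabeledDataset
    from .shorttime import FrameGrid

    rng = np.random.default_rng(seed)
    grid = FrameGrid.from_ms(sample_rate)
    bank = build_filterbank(sample_rate=sample_rate)
    cfg = CepstralConfig(use_lpcc=use_lpcc)
    cough_params = CoughEventParams()

    rows, labels = [], []
    for i in range(n_segments):
        if i % 2 == 0:
            w = generate_cough(cough_params, sample_rate, rng)
            label = "Cough"
        else:
            kind = DISTRACTOR_KINDS[(i // 2) % len(DISTRACTOR_KINDS)]
            w = generate_distractor(kind, _DISTRACTOR_DUR_S[kind], sample_rate, rng)
            label = "Noise"
        floor_rms = float(np.sqrt(np.mean(w**2))) * 10.0 ** (-snr_db / 20.0)
        clip = w + floor_rms * rng.standard_normal(len(w))
        rows.append(segment_features(clip, grid, bank, cfg).values)
        labels.append(label)
    return LabeledDataset(np.vstack(rows), np.asarray(labels))
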