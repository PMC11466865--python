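"""Cepstral features: mel filterbank, MFCC, LPC/LPCC, segment descriptors.

The mel scale here is ``F_mel(f) = 1125 ln(1 + f/700)`` (the natural-log
form of the usual 2595 log10 warping).  MFCCs are the discrete cosine
transform of the log filterbank energies:

    mfcc(n) = sqrt(2/M) * sum_{m=1..M} log S(m) * cos(pi n (2m-1) / (2M))

so a constant log-energy profile (silence, or any flat spectrum) maps to
exactly zero for every n >= 1.  LPCCs are obtained from the
linear-prediction coefficients ``a_1..a_p`` (autocorrelation method) by
the standard recursion

    c(1) = a_1
    c(n) = a_n + sum_{i=1..n-1} (1 - i/n) a_i c(n-i)     1 < n <= p
    c(n) =       sum_{i=1..p}   (1 - i/n) a_i c(n-i)     n > p

which is the cepstrum of the all-pole synthesis filter 1/(1 - sum a_i z^-i).

A candidate segment is summarised by the 17-dimensional vector
(mean amplitude, mean ZCR, max ZCR, mean energy, max energy,
mean MFCC 1..12), optionally extended by the 13-dimensional mean LPCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz

from .shorttime import FrameGrid, frame_signal, mean_amplitude, series_over_signal

_MEL_SCALE = 1125.0
_MEL_BREAK = 700.0


def hz_to_mel(f: float | np.ndarray) -> float | np.ndarray:
    """Warp frequency (Hz) to the perceptual mel scale."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = _MEL_SCALE * np.log1p(f / _MEL_BREAK)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(mel: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`hz_to_mel`."""
    mel = np.asarray(mel, dtype=np.float64)
    out = _MEL_BREAK * np.expm1(mel / _MEL_SCALE)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MelFilterbank:
    """M triangular filters over the rFFT bins, equally spaced in mel.

    ``weights`` has shape (n_filters, fft_size//2 + 1); each row rises
    linearly from bin ``f(m-1)`` to 1 at the center bin ``f(m)`` and falls
    to 0 at ``f(m+1)``.  Center bins are in ``center_bins`` (length M+2,
    including the edge points).
    """

    n_filters: int
    fft_size: int
    sample_rate: int
    f_low: float
    f_high: float
    weights: np.ndarray
    center_bins: np.ndarray


def build_filterbank(
    n_filters: int = 26,
    fft_size: int = 512,
    sample_rate: int = 8000,
    f_low: float = 30.0,
    f_high: float = 4000.0,
) -> MelFilterbank:
    """Construct the triangular mel filterbank.

    Center frequencies sit at ``mel(f_low) + m * (mel(f_high) -
    mel(f_low)) / (M+1)`` for m = 0..M+1 and are mapped to (rounded) rFFT
    bin numbers ``fft_size * f / sample_rate``; duplicate bins at the
    dense low end are pushed apart so each filter has nonempty support.
    """
    if not (0 <= f_low < f_high <= sample_rate / 2):
        raise ValueError(
            f"require 0 <= f_low < f_high <= sample_rate/2, "
            f"got f_low={f_low}, f_high={f_high}, sample_rate={sample_rate}"
        )
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    mel_pts = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_filters + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bins = np.round(fft_size * hz_pts / sample_rate).astype(int)
    for i in range(1, len(bins)):  # enforce strictly increasing bins
        if bins[i] <= bins[i - 1]:
            bins[i] = bins[i - 1] + 1
    n_bins = fft_size // 2 + 1
    if bins[-1] >= n_bins:
        raise ValueError("filterbank upper edge exceeds the rFFT bin range")
    k = np.arange(n_bins, dtype=np.float64)
    weights = np.zeros((n_filters, n_bins))
    for m in range(1, n_filters + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        rise = (k - left) / (center - left)
        fall = (right - k) / (right - center)
        tri = np.minimum(rise, fall)
        weights[m - 1] = np.where((k >= left) & (k <= right), np.maximum(tri, 0.0), 0.0)
    return MelFilterbank(
        n_filters=n_filters,
        fft_size=fft_size,
        sample_rate=sample_rate,
        f_low=f_low,
        f_high=f_high,
        weights=weights,
        center_bins=bins.astype(np.float64),
    )


@dataclass(frozen=True)
class CepstralConfig:
    """Cepstral feature configuration.

    ``n_lpcc`` may exceed ``lpc_order``: the LPCC recursion extends past
    the model order.  ``log_floor`` keeps the log of silent filterbank
    energies finite.
    """

    n_mfcc: int = 12
    n_lpcc: int = 13
    lpc_order: int = 12
    pre_emphasis: float = 0.97
    log_floor: float = 1e-10
    use_lpcc: bool = False

    def __post_init__(self) -> None:
        if self.log_floor <= 0:
            raise ValueError("log_floor must be > 0")
        if min(self.n_mfcc, self.n_lpcc, self.lpc_order) < 1:
            raise ValueError("n_mfcc, n_lpcc and lpc_order must be >= 1")


def filterbank_energies(frame: np.ndarray, bank: MelFilterbank) -> np.ndarray:
    """Power spectrum of one (zero-padded) frame through the filterbank."""
    x = np.asarray(frame, dtype=np.float64)
    if x.size > bank.fft_size:
        raise ValueError(
            f"frame of {x.size} samples exceeds fft_size {bank.fft_size}"
        )
    spectrum = np.fft.rfft(x, n=bank.fft_size)
    power = np.abs(spectrum) ** 2
    return bank.weights @ power


def mfcc_frame(
    frame: np.ndarray, bank: MelFilterbank, cfg: CepstralConfig = CepstralConfig()
) -> np.ndarray:
    """MFCC coefficients 1..n_mfcc of one frame (the constant term is
    omitted: it duplicates the energy feature)."""
    s = np.maximum(filterbank_energies(frame, bank), cfg.log_floor)
    log_s = np.log(s)
    m_idx = np.arange(1, bank.n_filters + 1)
    n_idx = np.arange(1, cfg.n_mfcc + 1)
    kernel = np.cos(np.pi * np.outer(n_idx, 2 * m_idx - 1) / (2.0 * bank.n_filters))
    return np.sqrt(2.0 / bank.n_filters) * (kernel @ log_s)


def lpc_coefficients(frame: np.ndarray, order: int) -> tuple[np.ndarray, bool]:
    """Forward linear-prediction coefficients a_1..a_p by the
    autocorrelation method (x(n) ~ sum_i a_i x(n-i)).

    Returns ``(a, degenerate)``: an all-zero (or too-short) frame yields a
    zero vector with ``degenerate=True`` instead of an error, so feature
    extraction never aborts on silence.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.size <= order:
        return np.zeros(order), True
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0.0:
        return np.zeros(order), True
    r = r / r[0]
    r0 = r[:order].copy()
    r0[0] += 1e-9  # ridge for numerically singular autocorrelations
    try:
        a = solve_toeplitz((r0, r0), r[1 : order + 1])
    except np.linalg.LinAlgError:
        return np.zeros(order), True
    if not np.all(np.isfinite(a)):
        return np.zeros(order), True
    return a, False


def lpcc_from_lpc(a: np.ndarray, n_out: int = 13) -> np.ndarray:
    """Cepstral coefficients c(1)..c(n_out) from LPC coefficients."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    a = np.asarray(a, dtype=np.float64)
    p = a.size
    c = np.zeros(n_out)
    for n in range(1, n_out + 1):
        acc = a[n - 1] if n <= p else 0.0
        for i in range(1, min(n - 1, p) + 1):
            acc += (1.0 - i / n) * a[i - 1] * c[n - i - 1]
        c[n - 1] = acc
    return c


@dataclass(frozen=True)
class FeatureVector:
    """Per-segment descriptor: values plus the column names, with a flag
    marking segments shorter than one frame (zero-padded up)."""

    values: np.ndarray
    names: tuple[str, ...]
    padded: bool = False


def feature_names(use_lpcc: bool = False, n_mfcc: int = 12, n_lpcc: int = 13) -> tuple[str, ...]:
    names = ["mean_amp", "mean_zcr", "max_zcr", "mean_energy", "max_energy"]
    names += [f"mfcc_{i:02d}" for i in range(1, n_mfcc + 1)]
    if use_lpcc:
        names += [f"lpcc_{i:02d}" for i in range(1, n_lpcc + 1)]
    return tuple(names)


def segment_features(
    segment_audio: np.ndarray,
    grid: FrameGrid,
    bank: MelFilterbank,
    cfg: CepstralConfig = CepstralConfig(),
) -> FeatureVector:
    """17-dim (or 30-dim with LPCC) descriptor of one candidate segment.

    Order: mean amplitude, mean ZCR, max ZCR, mean energy, max energy,
    then the per-frame MFCCs averaged over the segment, then (optionally)
    the mean LPCCs.  Pre-emphasis is applied before LPC only.
    """
    x = np.asarray(segment_audio, dtype=np.float64)
    padded = False
    if x.size < grid.frame_len:
        x = np.pad(x, (0, grid.frame_len - x.size))
        padded = True

    amp = mean_amplitude(x)
    zcr = series_over_signal(x, grid, "zcr").values
    energy = series_over_signal(x, grid, "energy").values
    frames = frame_signal(x, grid)
    mfccs = np.stack([mfcc_frame(f, bank, cfg) for f in frames])
    values = [amp, float(zcr.mean()), float(zcr.max()),
              float(energy.mean()), float(energy.max())]
    values.extend(mfccs.mean(axis=0))

    if cfg.use_lpcc:
        pre = np.empty_like(x)
        pre[0] = x[0]
        pre[1:] = x[1:] - cfg.pre_emphasis * x[:-1]
        lpccs = []
        for f in frame_signal(pre, grid):
            a, degenerate = lpc_coefficients(f, cfg.lpc_order)
            lpccs.append(np.zeros(cfg.n_lpcc) if degenerate else lpcc_from_lpc(a, cfg.n_lpcc))
        values.extend(np.stack(lpccs).mean(axis=0))

    return FeatureVector(
        values=np.asarray(values, dtype=np.float64),
        names=feature_names(cfg.use_lpcc, cfg.n_mfcc, cfg.n_lpcc),
        padded=padded,
    )
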