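"""Independent brute-force oracles used by the cepstral tests.

Everything here is written from first principles (explicit DFT sums,
piecewise triangle evaluation, long-FFT log-magnitude cepstrum) and never
calls into the package, so agreement is evidence of correctness rather
than self-consistency.
"""

import numpy as np

MEL_K = 1125.0


def mel(f):
    return MEL_K * np.log(1.0 + np.asarray(f, dtype=float) / 700.0)


def imel(m):
    return 700.0 * (np.exp(np.asarray(m, dtype=float) / MEL_K) - 1.0)


def center_bins(n_filters, fft_size, sample_rate, f_low, f_high):
    """Equal-mel center frequencies mapped to rounded, deduplicated bins."""
    pts = np.linspace(mel(f_low), mel(f_high), n_filters + 2)
    bins = np.round(fft_size * imel(pts) / sample_rate).astype(int)
    for i in range(1, len(bins)):
        if bins[i] <= bins[i - 1]:
            bins[i] = bins[i - 1] + 1
    return bins


def triangle_weight(k, left, center, right):
    """Piecewise-linear triangular response at integer bin k."""
    if k < left or k > right:
        return 0.0
    if k <= center:
        return (k - left) / (center - left)
    return (right - k) / (right - center)


def mfcc_bruteforce(frame, n_filters, fft_size, sample_rate, f_low, f_high,
                    n_mfcc, log_floor):
    """MFCCs via an explicit DFT, triangle evaluation and cosine sum."""
    x = np.zeros(fft_size)
    x[: len(frame)] = frame
    n_bins = fft_size // 2 + 1
    k_idx = np.arange(fft_size)
    power = np.empty(n_bins)
    for k in range(n_bins):  # explicit DFT, no FFT
        expo = np.exp(-2j * np.pi * k * k_idx / fft_size)
        power[k] = np.abs(np.sum(x * expo)) ** 2
    bins = center_bins(n_filters, fft_size, sample_rate, f_low, f_high)
    log_s = np.empty(n_filters)
    for m in range(1, n_filters + 1):
        s = sum(
            triangle_weight(k, bins[m - 1], bins[m], bins[m + 1]) * power[k]
            for k in range(n_bins)
        )
        log_s[m - 1] = np.log(max(s, log_floor))
    out = np.empty(n_mfcc)
    for n in range(1, n_mfcc + 1):
        out[n - 1] = np.sqrt(2.0 / n_filters) * sum(
            log_s[m - 1] * np.cos(np.pi * n * (2 * m - 1) / (2.0 * n_filters))
            for m in range(1, n_filters + 1)
        )
    return out


def lpc_from_reflection(k):
    """Levinson step-up: reflection coefficients -> stable LPC vector a
    (convention x(n) ~ sum a_i x(n-i), so the polynomial is 1 - sum a_i z^-i)."""
    a = np.array([], dtype=float)
    for km in k:
        a = np.concatenate([a - km * a[::-1], [km]]) if a.size else np.array([km])
    return a


def lpcc_fft_cepstrum(a, n_out, n_fft=1 << 20):
    """Cepstrum of 1/(1 - sum a_i z^-i) via the log-magnitude spectrum.

    For a minimum-phase filter the complex cepstrum is causal, so
    c(n) = 2 * real-cepstrum(n) for n >= 1.  The FFT grid is long because
    stacked reflection coefficients can push poles very close to the unit
    circle, where the cepstrum decays slowly and a short grid aliases it.
    """
    poly = np.zeros(n_fft)
    poly[0] = 1.0
    poly[1 : len(a) + 1] = -np.asarray(a)
    spectrum = np.fft.fft(poly)
    log_mag = np.log(np.abs(1.0 / spectrum))
    c = np.fft.ifft(log_mag).real
    return 2.0 * c[1 : n_out + 1]
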