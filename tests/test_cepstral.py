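import numpy as np
import pytest

import coughcount as cc
import oracles


def test_mel_scale_fixed_points():
    assert cc.hz_to_mel(0.0) == 0.0
    assert cc.hz_to_mel(700.0) == pytest.approx(1125 * np.log(2), rel=1e-12)
    assert cc.hz_to_mel(700.0) == pytest.approx(779.79, abs=0.01)


@pytest.mark.parametrize("f", [30.0, 440.0, 4000.0])
def test_mel_inverse_roundtrip(f):
    assert cc.mel_to_hz(cc.hz_to_mel(f)) == pytest.approx(f, abs=1e-9)


def test_mel_rejects_negative_frequency():
    with pytest.raises(ValueError):
        cc.hz_to_mel(-1.0)


def test_filterbank_rows_peak_at_one_inside_band(bank):
    assert bank.weights.shape == (26, 257)
    np.testing.assert_allclose(bank.weights.max(axis=1), 1.0)
    # support strictly inside the [f_low, f_high] bin range
    lo_bin, hi_bin = bank.center_bins[0], bank.center_bins[-1]
    occupied = np.flatnonzero(bank.weights.sum(axis=0) > 0)
    assert occupied.min() > lo_bin - 1 and occupied.max() < hi_bin + 1


def test_adjacent_filters_sum_to_one_between_centers(bank):
    bins = bank.center_bins.astype(int)
    for m in range(bank.n_filters - 1):
        lo, hi = bins[m + 1], bins[m + 2]  # centers of filters m and m+1
        for k in range(lo, hi + 1):
            total = bank.weights[m, k] + bank.weights[m + 1, k]
            assert total == pytest.approx(1.0, abs=1e-12)


def test_single_filter_bank_is_one_triangle():
    bank1 = cc.build_filterbank(n_filters=1, fft_size=512, sample_rate=8000,
                                f_low=100.0, f_high=3000.0)
    row = bank1.weights[0]
    peak = int(np.argmax(row))
    assert row[peak] == 1.0
    assert np.all(np.diff(row[: peak + 1]) >= -1e-12)  # unimodal rise
    assert np.all(np.diff(row[peak:]) <= 1e-12)        # then fall
    mid_hz = cc.mel_to_hz((cc.hz_to_mel(100.0) + cc.hz_to_mel(3000.0)) / 2)
    assert peak == pytest.approx(512 * mid_hz / 8000, abs=1.0)


def test_filterbank_validation():
    with pytest.raises(ValueError):
        cc.build_filterbank(f_low=5000.0, f_high=4000.0)
    with pytest.raises(ValueError):
        cc.build_filterbank(n_filters=0)


def test_mfcc_of_silence_is_zero(bank):
    out = cc.mfcc_frame(np.zeros(200), bank)
    assert out.shape == (12,)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_mfcc_of_white_noise_matches_flat_spectrum_closed_form():
    """For white noise E|X_k|^2 is constant, so the expected log filterbank
    energies are log(const * filter area) and the mean MFCCs converge to
    the DCT of the log filter areas (the constant vanishes for n >= 1)."""
    rng = np.random.default_rng(0)
    cfg = cc.CepstralConfig()
    wide = cc.build_filterbank(fft_size=4096)
    coeffs = np.mean(
        [cc.mfcc_frame(rng.standard_normal(4096), wide, cfg) for _ in range(50)],
        axis=0,
    )
    log_area = np.log(wide.weights.sum(axis=1))
    m = np.arange(1, wide.n_filters + 1)
    n = np.arange(1, cfg.n_mfcc + 1)
    kernel = np.cos(np.pi * np.outer(n, 2 * m - 1) / (2 * wide.n_filters))
    expected = np.sqrt(2 / wide.n_filters) * kernel @ log_area
    np.testing.assert_allclose(coeffs, expected, atol=0.15)


def test_mfcc_matches_bruteforce_oracle(bank):
    rng = np.random.default_rng(1)
    cfg = cc.CepstralConfig()
    for _ in range(5):
        frame = rng.standard_normal(200)
        ours = cc.mfcc_frame(frame, bank, cfg)
        ref = oracles.mfcc_bruteforce(frame, 26, 512, 8000, 30.0, 4000.0, 12,
                                      cfg.log_floor)
        np.testing.assert_allclose(ours, ref, atol=1e-8)


def test_mfcc_invariances(bank):
    rng = np.random.default_rng(2)
    # periodic frame: circular shift leaves the magnitude spectrum alone
    t = np.arange(512)
    frame = np.sin(2 * np.pi * 8 * t / 512) + 0.5 * np.sin(2 * np.pi * 40 * t / 512)
    shifted = np.roll(frame, 37)
    np.testing.assert_allclose(
        cc.mfcc_frame(frame, bank), cc.mfcc_frame(shifted, bank), atol=1e-6
    )
    # scaling adds a constant to the log energies; the DCT removes it
    frame = rng.standard_normal(512)
    np.testing.assert_allclose(
        cc.mfcc_frame(frame, bank), cc.mfcc_frame(5.0 * frame, bank), atol=1e-6
    )


def test_mfcc_rejects_overlong_frame(bank):
    with pytest.raises(ValueError):
        cc.mfcc_frame(np.zeros(513), bank)


def test_lpc_recovers_ar1_coefficient():
    rng = np.random.default_rng(3)
    x = np.zeros(4000)
    for n in range(1, 4000):
        x[n] = 0.9 * x[n - 1] + rng.standard_normal()
    a, degenerate = cc.lpc_coefficients(x, 1)
    assert not degenerate
    assert a[0] == pytest.approx(0.9, abs=0.05)


def test_lpc_of_white_noise_is_small():
    x = np.random.default_rng(4).standard_normal(8000)
    a, degenerate = cc.lpc_coefficients(x, 4)
    assert not degenerate
    assert np.all(np.abs(a) < 0.1)


def test_lpc_of_silence_is_flagged_degenerate():
    a, degenerate = cc.lpc_coefficients(np.zeros(100), 4)
    assert degenerate
    np.testing.assert_array_equal(a, 0.0)


def test_lpcc_hand_traced_single_pole():
    out = cc.lpcc_from_lpc(np.array([0.5]), 3)
    np.testing.assert_allclose(out, [0.5, 0.125, 1 / 24], atol=1e-9)


def test_lpcc_of_zero_lpc_is_zero():
    np.testing.assert_array_equal(cc.lpcc_from_lpc(np.zeros(12), 13), 0.0)


def test_lpcc_matches_fft_cepstrum_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        p = int(rng.integers(1, 13))
        k = rng.uniform(-0.9, 0.9, p)
        a = oracles.lpc_from_reflection(k)
        ours = cc.lpcc_from_lpc(a, 13)
        ref = oracles.lpcc_fft_cepstrum(a, 13)
        np.testing.assert_allclose(ours, ref, atol=1e-6)


def test_segment_feature_dimensions(grid, bank):
    rng = np.random.default_rng(6)
    x = rng.standard_normal(4000) * 0.3
    plain = cc.segment_features(x, grid, bank, cc.CepstralConfig())
    assert plain.values.shape == (17,)
    assert plain.names[:5] == ("mean_amp", "mean_zcr", "max_zcr",
                               "mean_energy", "max_energy")
    with_lpcc = cc.segment_features(x, grid, bank, cc.CepstralConfig(use_lpcc=True))
    assert with_lpcc.values.shape == (30,)
    assert with_lpcc.names[-1] == "lpcc_13"


def test_segment_features_of_silence_are_zero(grid, bank):
    out = cc.segment_features(np.zeros(2000), grid, bank)
    np.testing.assert_allclose(out.values, 0.0, atol=1e-12)


def test_segment_energy_aggregation(grid, bank):
    # two non-overlapping frames with energies 2 and 6
    grid2 = cc.FrameGrid(frame_len=4, hop=4)
    x = np.concatenate([np.sqrt([0.5, 0.5, 0.5, 0.5]), np.sqrt([1.5, 1.5, 1.5, 1.5])])
    out = cc.segment_features(x, grid2, bank)
    names = dict(zip(out.names, out.values))
    assert names["mean_energy"] == pytest.approx(4.0)
    assert names["max_energy"] == pytest.approx(6.0)


def test_subframe_segment_is_padded_and_flagged(grid, bank):
    out = cc.segment_features(np.ones(50) * 0.1, grid, bank)
    assert out.padded
    assert out.values.shape == (17,)


def test_cepstral_config_validation():
    with pytest.raises(ValueError):
        cc.CepstralConfig(log_floor=0.0)
    with pytest.raises(ValueError):
        cc.CepstralConfig(n_mfcc=0)
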