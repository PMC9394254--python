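"""Butterworth filtering, wavelet denoising and Welch band power."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from cceeg.preprocessing import (
    BANDS,
    EEGEpoch,
    FilterSpec,
    WaveletSpec,
    band_power,
    butterworth_lowpass,
    preprocess,
    wavelet_denoise,
)


def make_epoch(sig: np.ndarray, fs: float = 128.0) -> EEGEpoch:
    sig = np.atleast_2d(sig)
    names = tuple(f"ch{i}" for i in range(sig.shape[0]))
    return EEGEpoch(signal=sig, channel_names=names, fs_hz=fs)


# --- Butterworth -----------------------------------------------------------


def test_dc_gain_is_unity():
    epoch = make_epoch(np.full(1024, 3.7))
    out = butterworth_lowpass(epoch, FilterSpec(fs_hz=128))
    assert np.allclose(out.signal, 3.7, atol=1e-6)


def test_single_pass_magnitude_at_cutoff_is_minus_3db():
    spec = FilterSpec(order=3, cutoff_hz=30, fs_hz=512, zero_phase=False)
    sos = sp_signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs_hz,
                           output="sos")
    _, h = sp_signal.sosfreqz(sos, worN=[spec.cutoff_hz], fs=spec.fs_hz)
    assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=1e-6)


def test_60hz_attenuation_matches_analytic_butterworth_magnitude():
    """Steady-state amplitude of a 60 Hz tone after a 30 Hz order-3 low-pass.

    |H| = 1 / sqrt(1 + (60/30)^6) ~= 0.124, measured as RMS*sqrt(2) of the
    filtered signal with transients trimmed.  A high sampling rate keeps the
    bilinear-transform digital filter close to the analytic analog response.
    """
    fs, f0 = 4096.0, 60.0
    t = np.arange(int(8 * fs)) / fs
    epoch = make_epoch(np.sin(2 * np.pi * f0 * t), fs=fs)
    out = butterworth_lowpass(epoch, FilterSpec(order=3, cutoff_hz=30, fs_hz=fs,
                                                zero_phase=False))
    steady = out.signal[0, int(2 * fs):]
    amplitude = np.sqrt(2) * steady.std()
    expected = 1 / np.sqrt(1 + (f0 / 30) ** 6)
    assert amplitude == pytest.approx(expected, rel=0.02)


def test_zero_phase_squares_the_magnitude_response():
    fs, f0 = 4096.0, 60.0
    t = np.arange(int(8 * fs)) / fs
    epoch = make_epoch(np.sin(2 * np.pi * f0 * t), fs=fs)
    out = butterworth_lowpass(epoch, FilterSpec(order=3, cutoff_hz=30, fs_hz=fs,
                                                zero_phase=True))
    steady = out.signal[0, int(2 * fs): -int(2 * fs)]
    amplitude = np.sqrt(2) * steady.std()
    expected = (1 / np.sqrt(1 + (f0 / 30) ** 6)) ** 2
    assert amplitude == pytest.approx(expected, rel=0.05)


def test_filter_is_linear(rng):
    x = rng.standard_normal((2, 512))
    y = rng.standard_normal((2, 512))
    spec = FilterSpec(fs_hz=128)
    fx = butterworth_lowpass(make_epoch(x), spec).signal
    fy = butterworth_lowpass(make_epoch(y), spec).signal
    fxy = butterworth_lowpass(make_epoch(2.0 * x - 0.5 * y), spec).signal
    assert np.allclose(fxy, 2.0 * fx - 0.5 * fy, atol=1e-9)


def test_zero_phase_filtering_has_no_group_delay(rng):
    """Cross-correlation peak of a band-limited pulse with its filtered self is at lag 0."""
    fs = 128.0
    t = np.arange(1024) / fs
    pulse = np.exp(-0.5 * ((t - 4.0) / 0.3) ** 2) * np.sin(2 * np.pi * 5 * t)
    out = butterworth_lowpass(make_epoch(pulse, fs=fs), FilterSpec(fs_hz=fs)).signal[0]
    xc = np.correlate(out, pulse, mode="full")
    assert np.argmax(xc) == pulse.size - 1


def test_cutoff_at_nyquist_rejected():
    with pytest.raises(ValueError):
        FilterSpec(cutoff_hz=64, fs_hz=128)


def test_non_finite_input_rejected():
    sig = np.zeros((1, 64))
    sig[0, 10] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        butterworth_lowpass(make_epoch(sig), FilterSpec(fs_hz=128))


# --- wavelet denoising -----------------------------------------------------


def test_denoise_zero_signal_stays_zero():
    out = wavelet_denoise(make_epoch(np.zeros((3, 256))))
    assert np.allclose(out.signal, 0.0)


def test_denoise_reduces_mse_on_noisy_sinusoid():
    """MSE to the clean signal shrinks for >= 95% of 100 seeded replicates."""
    fs, n = 128.0, 1024
    t = np.arange(n) / fs
    clean = np.sin(2 * np.pi * 10 * t)
    wins = 0
    for seed in range(100):
        noisy = clean + np.random.default_rng(seed).normal(0, 0.5, n)
        out = wavelet_denoise(make_epoch(noisy, fs=fs)).signal[0]
        if np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2):
            wins += 1
    assert wins >= 95


def test_denoise_barely_changes_smooth_noise_free_signal():
    t = np.arange(1024) / 128.0
    smooth = np.sin(2 * np.pi * 2 * t) + 0.5 * np.cos(2 * np.pi * 0.5 * t)
    out = wavelet_denoise(make_epoch(smooth)).signal[0]
    rel_change = np.linalg.norm(out - smooth) / np.linalg.norm(smooth)
    assert rel_change < 0.05


def test_denoise_rejects_too_short_signal():
    with pytest.raises(ValueError, match="64"):
        wavelet_denoise(make_epoch(np.ones((1, 32))), WaveletSpec(level=6))


def test_denoise_preserves_shape_and_channel_order(rng):
    sig = rng.standard_normal((5, 300))
    sig[2] += 10.0  # marked channel
    out = wavelet_denoise(make_epoch(sig))
    assert out.signal.shape == (5, 300)
    assert out.channel_names == tuple(f"ch{i}" for i in range(5))
    assert out.signal[2].mean() > 5  # channel 2 still the offset one


# --- composed chain --------------------------------------------------------


def test_preprocess_zero_epoch_is_zero():
    out = preprocess(make_epoch(np.zeros((2, 512))))
    assert np.allclose(out.signal, 0.0)
    assert out.signal.shape == (2, 512)


def test_preprocess_preserves_full_scale_shape(rng):
    sig = rng.standard_normal((40, 8064)).astype(np.float32)
    names = tuple(f"c{i}" for i in range(40))
    out = preprocess(EEGEpoch(signal=sig, channel_names=names, fs_hz=128.0))
    assert out.signal.shape == (40, 8064)


def test_preprocess_mse_not_worse_than_noisy_input():
    fs, n = 128.0, 1024
    t = np.arange(n) / fs
    clean = np.sin(2 * np.pi * 10 * t)
    wins = 0
    for seed in range(20):
        noisy = clean + np.random.default_rng(seed).normal(0, 0.5, n)
        out = preprocess(make_epoch(noisy, fs=fs)).signal[0]
        if np.mean((out - clean) ** 2) <= np.mean((noisy - clean) ** 2):
            wins += 1
    assert wins >= 19


# --- band power ------------------------------------------------------------


def test_band_power_zero_signal_is_zero():
    epoch = make_epoch(np.zeros((3, 512)))
    for band in BANDS.values():
        assert np.allclose(band_power(epoch, band), 0.0)


def test_band_power_concentrates_on_tone_frequency():
    fs, n = 128.0, 8064
    t = np.arange(n) / fs
    epoch = make_epoch(np.sin(2 * np.pi * 10 * t), fs=fs)
    alpha = band_power(epoch, BANDS["alpha"])[0]
    total = band_power(epoch, (0.0, fs / 2))[0]
    assert alpha / total >= 0.90


def test_band_power_white_noise_share_tracks_bandwidth():
    fs, n = 128.0, 8064
    shares = []
    for seed in range(20):
        sig = np.random.default_rng(seed).standard_normal(n)
        epoch = make_epoch(sig, fs=fs)
        shares.append(
            band_power(epoch, BANDS["alpha"])[0] / band_power(epoch, (0.0, fs / 2))[0]
        )
    expected = (BANDS["alpha"][1] - BANDS["alpha"][0]) / (fs / 2)
    assert np.mean(shares) == pytest.approx(expected, rel=0.15)


def test_band_power_rejects_invalid_band():
    epoch = make_epoch(np.zeros((1, 256)))
    with pytest.raises(ValueError):
        band_power(epoch, (30.0, 10.0))
    with pytest.raises(ValueError):
        band_power(epoch, (10.0, 100.0))
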