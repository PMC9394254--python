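"""Signal conditioning for multichannel EEG epochs.

The chain is a third-order Butterworth low-pass (default cutoff 30 Hz,
keeping the delta-beta range where most task-relevant EEG power lives)
followed by wavelet-threshold denoising, applied independently per channel.
Welch band power provides the spectral (PSD) features used by the channel
analyses.

Filtering is zero-phase (forward-backward, ``scipy.signal.filtfilt``) by
default: the analysis is offline, so the group delay of a causal pass is
pure nuisance.  With zero-phase filtering the effective magnitude response
is the squared single-pass Butterworth response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pywt
from scipy import signal

from cceeg.labeling import SamRating

__all__ = [
    "EEGEpoch",
    "FilterSpec",
    "WaveletSpec",
    "butterworth_lowpass",
    "wavelet_denoise",
    "preprocess",
    "band_power",
    "BANDS",
]

#: Canonical EEG frequency bands (Hz).
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class EEGEpoch:
    """One trial: channels x time signal (µV) with montage and sampling rate."""

    signal: np.ndarray
    channel_names: tuple[str, ...]
    fs_hz: float
    rating: Optional[SamRating] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x time)")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.signal.shape[1] < 8:
            raise ValueError("epoch must contain at least 8 samples")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("epoch contains non-finite samples")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass configuration."""

    order: int = 3
    cutoff_hz: float = 30.0
    fs_hz: float = 128.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist="
                f"{self.fs_hz / 2} Hz)"
            )


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet-threshold denoising configuration.

    Universal threshold sigma * sqrt(2 ln N) with sigma estimated from the
    median absolute deviation of the finest detail coefficients
    (MAD / 0.6745), applied to all detail levels.  Defaults are sym8 at
    level 4 with hard thresholding: EEG rhythms are oscillatory, hence not
    sparse in the wavelet domain, and soft thresholding biases their large
    in-band detail coefficients by the full threshold; hard thresholding
    keeps them intact while still zeroing noise-only coefficients.  Soft
    mode remains available for sparse/transient signals.
    """

    family: str = "sym8"
    level: int = 4
    threshold_rule: str = "universal"
    mode: str = "hard"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.mode not in ("soft", "hard"):
            raise ValueError(f"threshold mode must be 'soft' or 'hard', got {self.mode!r}")


def butterworth_lowpass(epoch: EEGEpoch, spec: FilterSpec | None = None) -> EEGEpoch:
    """Low-pass every channel; zero-phase by default (DC gain preserved)."""
    if spec is None:
        spec = FilterSpec(fs_hz=epoch.fs_hz)
    epoch.require_finite()
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs_hz,
                        output="sos")
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, epoch.signal, axis=1)
    else:
        filtered = signal.sosfilt(sos, epoch.signal, axis=1)
    return replace(epoch, signal=filtered)


def _denoise_channel(x: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    coeffs = pywt.wavedec(x, spec.family, level=spec.level)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(x.size))
    if threshold == 0.0:  # noise-free (e.g. all-zero) channel
        return x.copy()
    coeffs = [coeffs[0]] + [
        pywt.threshold(c, threshold, mode=spec.mode) for c in coeffs[1:]
    ]
    return pywt.waverec(coeffs, spec.family)[: x.size]


def wavelet_denoise(epoch: EEGEpoch, spec: WaveletSpec | None = None) -> EEGEpoch:
    """Multilevel wavelet-threshold denoising of every channel."""
    if spec is None:
        spec = WaveletSpec()
    epoch.require_finite()
    min_len = 2 ** spec.level
    if epoch.n_samples < min_len:
        raise ValueError(
            f"signal length {epoch.n_samples} too short for a level-"
            f"{spec.level} decomposition (needs >= {min_len} samples)"
        )
    denoised = np.vstack(
        [_denoise_channel(row, spec) for row in epoch.signal]
    )
    return replace(epoch, signal=denoised)


def preprocess(
    epoch: EEGEpoch,
    filter_spec: FilterSpec | None = None,
    wavelet_spec: WaveletSpec | None = None,
) -> EEGEpoch:
    """Butterworth low-pass, then wavelet denoise; shape preserved."""
    if filter_spec is None:
        filter_spec = FilterSpec(fs_hz=epoch.fs_hz)
    out = butterworth_lowpass(epoch, filter_spec)
    out = wavelet_denoise(out, wavelet_spec)
    assert out.signal.shape == epoch.signal.shape
    return out


def band_power(
    epoch: EEGEpoch, band: tuple[float, float], nperseg: int | None = None
) -> np.ndarray:
    """Welch power integrated over [f_lo, f_hi], per channel (nonnegative)."""
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= epoch.fs_hz / 2:
        raise ValueError(
            f"band {band} invalid for Nyquist {epoch.fs_hz / 2} Hz"
        )
    if nperseg is None:
        nperseg = min(epoch.n_samples, 256)
    freqs, psd = signal.welch(epoch.signal, fs=epoch.fs_hz, nperseg=nperseg, axis=1)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def band_power_features(epoch: EEGEpoch, bands: dict[str, tuple[float, float]] = BANDS) -> np.ndarray:
    """Flat (channel, band) power feature vector in band-sorted name order."""
    cols = [band_power(epoch, bands[name]) for name in sorted(bands)]
    return np.concatenate(cols)
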