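"""Labeled EEG-like epoch generator with planted, class-dependent band power.

Each of the nine emotion classes is assigned a (theta, alpha, beta)
amplitude triple.  A designated "informative" channel group (by default a
central/parietal-like set, mirroring where emotion-related signal was found
to concentrate) carries class-specific sinusoids with random phases on top
of 1/f (pink) and white noise; all other channels carry noise only.  Class
structure therefore lives entirely in band power on the informative
channels, which is exactly the handle the downstream ablation experiment
needs: removing those channels removes the class signal.

The default sizing mirrors the balanced nine-class design the classifier
targets: 500 epochs per class, 4500 in total, 40 channels x 8064 samples at
128 Hz.  All randomness flows through one explicit seed; per-epoch
generators are derived from it with ``numpy.random.SeedSequence`` spawn
keys, so any epoch is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from cceeg.preprocessing import EEGEpoch

__all__ = [
    "DEAP_EEG_CHANNELS",
    "DEAP_PERIPHERAL_CHANNELS",
    "deap_montage",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_amplitude_table",
    "generate_epoch",
    "generate_dataset",
    "desk_scale_config",
]

#: 32 EEG electrode names of the emulated montage (10-20 system).
DEAP_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Eight peripheral (non-EEG) channel placeholders.
DEAP_PERIPHERAL_CHANNELS: tuple[str, ...] = (
    "hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Plet", "Temp",
)

#: Informative group default: parietal/centro-parietal electrodes.
DEFAULT_INFORMATIVE: tuple[str, ...] = ("P3", "P4", "Pz", "CP1", "CP2", "CP5", "CP6")

#: Carrier frequencies (Hz) for the three planted bands.
BAND_FREQS = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}


def deap_montage() -> tuple[str, ...]:
    """Full 40-channel montage: 32 EEG electrodes + 8 peripheral channels."""
    return DEAP_EEG_CHANNELS + DEAP_PERIPHERAL_CHANNELS


def default_amplitude_table() -> dict[int, tuple[float, float, float]]:
    """Class ordinal -> (theta, alpha, beta) amplitudes.

    Theta amplitude increases with the valence level and beta with the
    arousal level, so the (theta, beta) pair is unique per class; alpha
    varies with their sum.  Steps of 1.5 against unit-SD white noise give a
    well-separated (but not trivially noiseless) band-power signature.
    """
    table = {}
    for ordinal in range(9):
        v_idx, a_idx = ordinal % 3, ordinal // 3
        table[ordinal] = (
            1.0 + 1.5 * v_idx,
            1.0 + 0.75 * (v_idx + a_idx),
            1.0 + 1.5 * a_idx,
        )
    return table


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic EEG generator."""

    n_channels: int = 40
    n_samples: int = 8064
    fs_hz: float = 128.0
    channel_names: tuple[str, ...] = field(default_factory=deap_montage)
    informative_channels: tuple[str, ...] = DEFAULT_INFORMATIVE
    amplitude_table: Mapping[int, tuple[float, float, float]] = field(
        default_factory=default_amplitude_table
    )
    background_noise_sd: float = 1.0
    pink_noise_scale: float = 1.0
    epochs_per_class: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        unknown = set(self.informative_channels) - set(self.channel_names)
        if unknown:
            raise ValueError(f"informative channels not in montage: {sorted(unknown)}")
        if self.epochs_per_class < 1:
            raise ValueError("epochs_per_class must be >= 1")
        if self.background_noise_sd < 0 or self.pink_noise_scale < 0:
            raise ValueError("noise scales must be nonnegative")
        for ordinal, amps in self.amplitude_table.items():
            if not 0 <= ordinal <= 8:
                raise ValueError(f"amplitude table ordinal {ordinal} outside 0-8")
            if any(a < 0 for a in amps):
                raise ValueError(f"negative amplitude for class {ordinal}")

    def to_manifest(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "fs_hz": self.fs_hz,
            "channel_names": list(self.channel_names),
            "informative_channels": list(self.informative_channels),
            "amplitude_table": {str(k): list(v) for k, v in self.amplitude_table.items()},
            "background_noise_sd": self.background_noise_sd,
            "pink_noise_scale": self.pink_noise_scale,
            "epochs_per_class": self.epochs_per_class,
            "seed": self.seed,
        }


@dataclass
class SyntheticDataset:
    """Generated epochs, their class ordinals and the generating manifest."""

    epochs: list[EEGEpoch]
    labels: np.ndarray
    manifest: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.epochs) != self.labels.size:
            raise ValueError("epoch/label count mismatch")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.epochs[0].channel_names

    def signal_array(self, dtype=np.float32) -> np.ndarray:
        """Stacked (n_epochs, n_channels, n_samples) array."""
        return np.stack([e.signal for e in self.epochs]).astype(dtype)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=9)


def _pink_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white Gaussian noise."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spectrum * shaping, n)
    sd = pink.std()
    return scale * pink / sd if sd > 0 else pink


def generate_epoch(class_ordinal: int, config: GeneratorConfig, seed: int) -> EEGEpoch:
    """One epoch of the given class; bit-identical for equal (ordinal, config, seed)."""
    if not 0 <= class_ordinal <= 8:
        raise ValueError(f"class ordinal {class_ordinal} outside 0-8")
    rng = np.random.default_rng(seed)
    n_ch, n = config.n_channels, config.n_samples
    t = np.arange(n) / config.fs_hz
    amps = config.amplitude_table[class_ordinal]
    informative = set(config.informative_channels)
    sig = np.empty((n_ch, n))
    for ch, name in enumerate(config.channel_names):
        row = rng.standard_normal(n) * config.background_noise_sd
        row += _pink_noise(rng, n, config.pink_noise_scale)
        if name in informative:
            for amp, freq in zip(amps, BAND_FREQS.values()):
                phase = rng.uniform(0, 2 * np.pi)
                row += amp * np.sin(2 * np.pi * freq * t + phase)
        sig[ch] = row
    return EEGEpoch(signal=sig, channel_names=config.channel_names, fs_hz=config.fs_hz)


def _epoch_seed(config: GeneratorConfig, index: int) -> int:
    return int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index,)).generate_state(1)[0]
    )


def iter_epochs(config: GeneratorConfig) -> Iterator[tuple[EEGEpoch, int]]:
    """Yield (epoch, ordinal) pairs in shuffled order without storing them all."""
    labels = np.repeat(np.arange(9), config.epochs_per_class)
    order = np.random.default_rng(config.seed).permutation(labels.size)
    for index in order:
        yield (
            generate_epoch(int(labels[index]), config, _epoch_seed(config, int(index))),
            int(labels[index]),
        )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Balanced nine-class dataset (epochs_per_class per ordinal), shuffled."""
    epochs, labels = [], []
    for epoch, ordinal in iter_epochs(config):
        epochs.append(epoch)
        labels.append(ordinal)
    return SyntheticDataset(
        epochs=epochs,
        labels=np.asarray(labels),
        manifest={"generator": config.to_manifest()},
    )


def well_separated_amplitude_table(scale: float = 4.0) -> dict[int, tuple[float, float, float]]:
    """A maximally separable class code: amplitudes step by ``scale`` per level.

    Theta tracks the valence level (0, scale, 2*scale), beta the arousal
    level, alpha their sum at half scale; with reduced noise this yields a
    class structure a capable classifier should recover almost perfectly,
    which is the regime the learning-behaviour and ablation contrasts need.
    """
    table = {}
    for ordinal in range(9):
        v_idx, a_idx = ordinal % 3, ordinal // 3
        table[ordinal] = (scale * v_idx, scale / 2 * (v_idx + a_idx), scale * a_idx)
    return table


def well_separated_config(epochs_per_class: int = 10, seed: int = 0, **overrides) -> GeneratorConfig:
    """Desk-scale config with the maximally separable amplitude code."""
    overrides.setdefault("amplitude_table", well_separated_amplitude_table())
    overrides.setdefault("background_noise_sd", 0.5)
    overrides.setdefault("pink_noise_scale", 0.5)
    return desk_scale_config(epochs_per_class=epochs_per_class, seed=seed, **overrides)


def desk_scale_config(
    epochs_per_class: int = 10,
    seed: int = 0,
    n_channels: int = 8,
    n_samples: int = 512,
    **overrides,
) -> GeneratorConfig:
    """Reduced-geometry configuration (8 channels x 512 samples by default).

    The montage keeps the parietal informative trio (P3, P4, Pz) plus five
    uninformative electrodes, so ablation contrasts remain expressible at
    small scale.
    """
    small_montage = ("P3", "P4", "Pz", "F3", "F4", "Fz", "O1", "O2")
    names = overrides.pop("channel_names", small_montage[:n_channels])
    informative = overrides.pop(
        "informative_channels",
        tuple(c for c in ("P3", "P4", "Pz") if c in names),
    )
    return GeneratorConfig(
        n_channels=n_channels,
        n_samples=n_samples,
        channel_names=tuple(names),
        informative_channels=tuple(informative),
        epochs_per_class=epochs_per_class,
        seed=seed,
        **overrides,
    )
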