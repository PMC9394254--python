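"""Epoch-container I/O and the optional DEAP preprocessed-file reader.

The canonical on-disk container is HDF5 with an explicit schema version:

* dataset ``signal``: float32, (n_epochs, n_channels, n_samples)
* dataset ``channel_names``: UTF-8 strings, length n_channels
* optional datasets ``labels`` (int ordinals), ``valence``, ``arousal``
* attrs: ``fs_hz`` (required), ``schema_version``

Coordinate conventions: channel axis first, time axis second, 0-based
indices, sampling rate carried as metadata.  DEAP's own serialized
per-subject format (a pickled dict with ``data`` (40, 40, 8064) and
``labels`` (40, 4)) is read-only and quarantined behind
:func:`read_deap_preprocessed`; the dataset is restricted-access and never
downloaded by this package.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import h5py
import numpy as np

from cceeg.labeling import SamRating, map_emotion
from cceeg.preprocessing import EEGEpoch
from cceeg.synthetic_data import SyntheticDataset, deap_montage

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_epoch_container",
    "read_epoch_container",
    "read_deap_preprocessed",
]

SCHEMA_VERSION = "cceeg-epochs-1"


class SchemaError(ValueError):
    """Container does not match the expected schema."""


def write_epoch_container(path: str | Path, dataset: SyntheticDataset) -> None:
    """Write a dataset to the HDF5 epoch container."""
    path = Path(path)
    signals = dataset.signal_array(dtype=np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=signals)
        f.create_dataset(
            "channel_names",
            data=np.array([n.encode() for n in dataset.channel_names]),
        )
        if dataset.labels is not None and dataset.labels.size:
            f.create_dataset("labels", data=dataset.labels.astype(np.int64))
        ratings = [e.rating for e in dataset.epochs]
        if all(r is not None for r in ratings):
            f.create_dataset("valence", data=np.array([r.valence for r in ratings]))
            f.create_dataset("arousal", data=np.array([r.arousal for r in ratings]))
        f.attrs["fs_hz"] = dataset.epochs[0].fs_hz
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["manifest"] = json.dumps(dataset.manifest)


def read_epoch_container(path: str | Path) -> SyntheticDataset:
    """Read the HDF5 epoch container back into a dataset.

    Epochs without stored labels get ordinal -1 (unlabeled) unless valence/
    arousal ratings are stored, in which case ordinals are derived through
    the 3x3 emotion mapping.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unrecognized schema_version {version!r} (expected {SCHEMA_VERSION!r})"
            )
        if "fs_hz" not in f.attrs:
            raise SchemaError("container missing required attribute 'fs_hz'")
        for name in ("signal", "channel_names"):
            if name not in f:
                raise SchemaError(f"container missing required dataset '{name}'")
        fs_hz = float(f.attrs["fs_hz"])
        signals = f["signal"][...]
        names = tuple(n.decode() for n in f["channel_names"][...])
        if signals.ndim != 3 or signals.shape[1] != len(names):
            raise SchemaError(
                f"dataset 'signal' shape {signals.shape} inconsistent with "
                f"{len(names)} channel names"
            )
        ratings = None
        if "valence" in f and "arousal" in f:
            ratings = [
                SamRating(float(v), float(a))
                for v, a in zip(f["valence"][...], f["arousal"][...])
            ]
        if "labels" in f:
            labels = f["labels"][...].astype(np.int64)
        elif ratings is not None:
            labels = np.array([map_emotion(r).ordinal for r in ratings])
        else:
            labels = np.full(signals.shape[0], -1, dtype=np.int64)
        manifest = json.loads(f.attrs.get("manifest", "{}"))
    epochs = [
        EEGEpoch(
            signal=signals[i],
            channel_names=names,
            fs_hz=fs_hz,
            rating=ratings[i] if ratings is not None else None,
        )
        for i in range(signals.shape[0])
    ]
    return SyntheticDataset(epochs=epochs, labels=labels, manifest=manifest)


def read_deap_preprocessed(path: str | Path, fs_hz: float = 128.0) -> SyntheticDataset:
    """Read one DEAP preprocessed per-subject file (optional input).

    Expects the pickled dict layout with ``data`` shaped (40 trials, 40
    channels, 8064 samples) and ``labels`` shaped (40, 4) where the first
    two columns are valence and arousal on the 1-9 scale.  The file must be
    obtained by the user through DEAP registration; nothing is downloaded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. DEAP is a restricted-access dataset: register at "
            "the DEAP website and download the preprocessed per-subject files "
            "yourself; this package never downloads them."
        )
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
        data = np.asarray(payload["data"])
        ratings = np.asarray(payload["labels"])
    except Exception as err:  # malformed file -> no partial dataset
        raise ValueError(f"could not parse {path} as a DEAP preprocessed file: {err}") from err
    if data.ndim != 3 or data.shape[1:] != (40, 8064):
        raise ValueError(
            f"per-trial arrays must be (40, 8064); got {data.shape[1:]} in {path}"
        )
    if ratings.shape != (data.shape[0], 4):
        raise ValueError(f"labels must be (n_trials, 4); got {ratings.shape}")
    montage = deap_montage()
    epochs, ordinals = [], []
    for trial in range(data.shape[0]):
        rating = SamRating(float(ratings[trial, 0]), float(ratings[trial, 1]))
        epochs.append(
            EEGEpoch(signal=data[trial], channel_names=montage, fs_hz=fs_hz, rating=rating)
        )
        ordinals.append(map_emotion(rating).ordinal)
    return SyntheticDataset(
        epochs=epochs,
        labels=np.array(ordinals),
        manifest={"source": "deap_preprocessed", "file": str(path)},
    )
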