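"""Cross-connected CNN construction.

Three parallel branches extract bottom-, middle- and top-level features
from the raw multichannel epoch: branch depths are one, two and three
conv/pool pairs.  Every conv is a width-3 kernel; the branch-initial conv
spans the full channel axis and collapses it to one feature map.  Each
branch ends in a dense layer of ``branch_dense_units`` (default 100); the
per-branch features are concatenated into the fused feature (default width
300) and mapped by a final dense + softmax onto the nine emotion classes.

Two topologies are supported and produce identical shape traces:

* ``parallel`` (default) — each branch owns its first conv, matching the
  branch tables which all start from the raw input;
* ``shared_stem`` — the first conv feature map is computed once and re-used
  by all branches.

Layer-depth variants append one or two further conv/pool blocks beyond the
top branch, each with its own 100-wide feature tap, widening the fused
feature by 100 per extra layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from cceeg import nn
from cceeg.core_shapes import (
    InvalidGeometryError,
    LayerSpec,
    ShapeTrace,
    default_branch_specs,
    trace_branch,
)
from cceeg.preprocessing import EEGEpoch

__all__ = [
    "ArchitectureSpec",
    "ModelHandle",
    "default_architecture",
    "build_model",
    "forward_probabilities",
    "extract_features",
    "make_variant",
]

FEATURE_LEVELS = ("bottom", "middle", "top", "fused")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the C-c CNN and its variants."""

    branches: tuple[tuple[LayerSpec, ...], ...] = field(
        default_factory=lambda: tuple(tuple(b) for b in default_branch_specs())
    )
    branch_dense_units: int = 100
    n_classes: int = 9
    topology: Literal["parallel", "shared_stem"] = "parallel"
    use_batchnorm: bool = True
    dropout_rate: float = 0.5
    extra_layers: int = 0

    def __post_init__(self) -> None:
        if len(self.branches) != 3:
            raise ValueError("exactly three branches (bottom, middle, top) expected")
        depths = [sum(1 for l in b if l.kind == "conv") for b in self.branches]
        if depths != [1, 2, 3]:
            raise ValueError(f"branch conv depths must be (1, 2, 3), got {tuple(depths)}")
        if self.extra_layers not in (0, 1, 2):
            raise ValueError("extra_layers must be 0, 1 or 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.topology not in ("parallel", "shared_stem"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.branch_dense_units < 1 or self.n_classes < 2:
            raise ValueError("branch_dense_units >= 1 and n_classes >= 2 required")

    @property
    def branch_depths(self) -> tuple[int, ...]:
        """Conv/pool pair count per branch, including variant taps."""
        return tuple(range(1, 4)) + tuple(4 + i for i in range(self.extra_layers))

    @property
    def fused_width(self) -> int:
        return (3 + self.extra_layers) * self.branch_dense_units

    def branch_layer_specs(self, input_channels: int) -> list[list[LayerSpec]]:
        """Conv/pool LayerSpec lists for each branch (incl. variant taps),
        with the branch-initial conv spanning ``input_channels``."""
        specs = []
        for depth in self.branch_depths:
            layers = [LayerSpec("input")]
            for i in range(depth):
                layers.append(
                    LayerSpec("conv", kernel_channels=input_channels if i == 0 else 1,
                              kernel_width=3, stride=1)
                )
                layers.append(LayerSpec("pool", kernel_width=2, stride=2))
            layers.append(LayerSpec("dense", units=self.branch_dense_units))
            layers.append(LayerSpec("dense", units=self.n_classes))
            specs.append(layers)
        return specs

    def shape_traces(self, input_channels: int, input_length: int) -> list[ShapeTrace]:
        """Shape trace per branch; geometry failures cite branch and layer."""
        traces = []
        for b_idx, layers in enumerate(self.branch_layer_specs(input_channels)):
            try:
                traces.append(trace_branch(layers, input_length, input_channels))
            except InvalidGeometryError as err:
                raise InvalidGeometryError(f"branch {b_idx}: {err}") from err
        return traces


def default_architecture(**overrides) -> ArchitectureSpec:
    return ArchitectureSpec(**overrides)


class _CcnnNetwork:
    """The assembled network: stem (optional), branch tails, fusion head."""

    def __init__(self, spec: ArchitectureSpec, input_channels: int,
                 input_length: int, rng: np.random.Generator):
        self.spec = spec
        self.input_channels = input_channels
        self.input_length = input_length
        self.dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.extra_convs: list[nn.Conv1] = []

        traces = spec.shape_traces(input_channels, input_length)
        # pre-dense length per branch: entry before the first dense layer
        pre_dense = [t.lengths[-3] for t in traces]

        def conv_block(first: bool) -> list[nn.Layer]:
            conv: nn.Layer = (
                nn.ChannelCollapseConv(input_channels, 3, rng) if first else nn.Conv1(3, rng)
            )
            block: list[nn.Layer] = [conv]
            if spec.use_batchnorm:
                block.append(nn.BatchNorm())
            block.append(nn.ReLU())
            return block

        self.stem: nn.Sequential | None = None
        if spec.topology == "shared_stem":
            self.stem = nn.Sequential(conv_block(first=True))

        self.branches: list[nn.Sequential] = []
        for depth, flat_len in zip(spec.branch_depths, pre_dense):
            layers: list[nn.Layer] = []
            for i in range(depth):
                if i == 0:
                    if self.stem is None:
                        layers += conv_block(first=True)
                else:
                    block = conv_block(first=False)
                    if i >= 3:
                        self.extra_convs.append(block[0])
                    layers += block
                layers.append(nn.MaxPoolHalf())
            if spec.dropout_rate > 0:
                layers.append(nn.Dropout(spec.dropout_rate, self.dropout_rng))
            layers.append(nn.Dense(flat_len, spec.branch_dense_units, rng))
            layers.append(nn.ReLU())
            self.branches.append(nn.Sequential(layers))

        head_layers: list[nn.Layer] = []
        if spec.dropout_rate > 0:
            head_layers.append(nn.Dropout(spec.dropout_rate, self.dropout_rng))
        head_layers.append(nn.Dense(spec.fused_width, spec.n_classes, rng))
        self.head = nn.Sequential(head_layers)

    # -- forward / backward -------------------------------------------------
    def branch_features(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        inp = self.stem.forward(x, training=training) if self.stem is not None else x
        return [b.forward(inp, training=training) for b in self.branches]

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        fused = np.concatenate(self.branch_features(x, training=training), axis=1)
        return self.head.forward(fused, training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        u = self.spec.branch_dense_units
        dstem = None
        for i, branch in enumerate(self.branches):
            g = branch.backward(dfused[:, i * u : (i + 1) * u])
            if self.stem is not None:
                dstem = g if dstem is None else dstem + g
        if self.stem is not None:
            self.stem.backward(dstem)

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        if self.stem is not None:
            out += self.stem.params()
        for b in self.branches:
            out += b.params()
        return out + self.head.params()

    def batchnorms(self) -> list[nn.BatchNorm]:
        groups = ([self.stem] if self.stem is not None else []) + self.branches + [self.head]
        return [l for seq in groups for l in seq.layers if isinstance(l, nn.BatchNorm)]


@dataclass
class ModelHandle:
    """An assembled (possibly trained) network plus its spec and geometry."""

    network: _CcnnNetwork
    spec: ArchitectureSpec
    input_channels: int
    input_length: int
    seed: int

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.network.params()))


def build_model(
    spec: ArchitectureSpec,
    input_channels: int,
    input_length: int,
    seed: int = 0,
) -> ModelHandle:
    """Build the network after validating branch geometry analytically."""
    spec.shape_traces(input_channels, input_length)  # raises on bad geometry
    rng = np.random.default_rng(seed)
    net = _CcnnNetwork(spec, input_channels, input_length, rng)
    return ModelHandle(net, spec, input_channels, input_length, seed)


def _as_batch(model: ModelHandle, epochs) -> np.ndarray:
    if isinstance(epochs, np.ndarray):
        batch = epochs
        if batch.ndim == 2:
            batch = batch[None]
    else:
        items = list(epochs)
        if items and isinstance(items[0], EEGEpoch):
            batch = np.stack([e.signal for e in items])
        else:
            batch = np.asarray(items)
    if batch.ndim != 3 or batch.shape[1:] != (model.input_channels, model.input_length):
        raise ValueError(
            f"batch shape {batch.shape} does not match model input "
            f"({model.input_channels} channels x {model.input_length} samples)"
        )
    return batch.astype(np.float64)


def forward_probabilities(model: ModelHandle, epochs) -> np.ndarray:
    """Class-probability rows (batch x n_classes); inference mode."""
    batch = _as_batch(model, epochs)
    return nn.softmax(model.network.forward_logits(batch, training=False))


def extract_features(model: ModelHandle, epochs, level: str) -> np.ndarray:
    """Per-branch dense features (batch x 100) or their fused concatenation.

    ``fused`` concatenates all branch taps column-wise (bottom, middle, top,
    then any variant taps), so its width is ``spec.fused_width``.
    """
    if level not in FEATURE_LEVELS:
        raise ValueError(f"unknown feature level {level!r}; expected one of {FEATURE_LEVELS}")
    batch = _as_batch(model, epochs)
    feats = model.network.branch_features(batch, training=False)
    if level == "fused":
        return np.concatenate(feats, axis=1)
    return feats[FEATURE_LEVELS.index(level)]


def make_variant(spec: ArchitectureSpec, extra_layers: int) -> ArchitectureSpec:
    """Variant with 0-2 conv/pool blocks (and feature taps) beyond the top branch."""
    if extra_layers not in (0, 1, 2):
        raise ValueError("extra_layers must be 0, 1 or 2")
    return replace(spec, extra_layers=extra_layers)


_SPEC_SCALARS = ("branch_dense_units", "n_classes", "topology", "use_batchnorm",
                 "dropout_rate", "extra_layers")


def spec_to_dict(spec: ArchitectureSpec) -> dict:
    """Scalar-field serialization; branch tables are canonical and rebuilt."""
    return {name: getattr(spec, name) for name in _SPEC_SCALARS}


def spec_from_dict(payload: dict) -> ArchitectureSpec:
    unknown = set(payload) - set(_SPEC_SCALARS)
    if unknown:
        raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
    return ArchitectureSpec(
        branches=tuple(
            tuple(b)
            for b in default_branch_specs(
                units=payload.get("branch_dense_units", 100),
                n_classes=payload.get("n_classes", 9),
            )
        ),
        **payload,
    )


def save_checkpoint(model: ModelHandle, path) -> None:
    """Weights as an .npz plus the spec/geometry needed for reconstruction."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.network.params())}
    bn_stats = np.array(
        [[bn.running_mean, bn.running_var] for bn in model.network.batchnorms()]
    )
    np.savez(path.with_suffix(".npz"), __bn_stats__=bn_stats, **arrays)
    meta = {
        "spec": spec_to_dict(model.spec),
        "input_channels": model.input_channels,
        "input_length": model.input_length,
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> ModelHandle:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(
        spec_from_dict(meta["spec"]), meta["input_channels"], meta["input_length"],
        seed=meta["seed"],
    )
    with np.load(path.with_suffix(".npz")) as arrays:
        params = model.network.params()
        if len(arrays.files) != len(params) + 1:
            raise ValueError("checkpoint parameter count does not match the spec")
        for i, p in enumerate(params):
            p.value[...] = arrays[f"p{i}"]
        for bn, (mean, var) in zip(model.network.batchnorms(), arrays["__bn_stats__"]):
            bn.running_mean, bn.running_var = float(mean), float(var)
    return model
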