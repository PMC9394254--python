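"""Analytic shape calculus for the C-c CNN branches.

Pure integer arithmetic, independent of any learning framework: every
printed layer size of the three branch tables (bottom / middle / top) must
be reproducible from these functions.

Conventions
-----------
* Convolution: valid (no padding), cross-correlation orientation.
* Pooling: non-overlapping window of 2, stride 2, with a trailing partial
  window kept, i.e. ``ceil(n / 2)``.  This is the only convention consistent
  with all printed pooled lengths (8062 -> 4031, 4029 -> 2015, 2013 -> 1007);
  the branch tables' pooling "stride" column is ignored in favour of the
  printed output lengths.
* The first convolution spans the full channel axis (kernel
  ``n_channels x 1 x 3``) and collapses it to a single feature map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "InvalidGeometryError",
    "LayerSpec",
    "ShapeTrace",
    "conv_output_length",
    "pool_output_length",
    "trace_branch",
    "bottom_branch_spec",
    "middle_branch_spec",
    "top_branch_spec",
    "default_branch_specs",
]


class InvalidGeometryError(ValueError):
    """Raised when a layer cannot be applied to its input length."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a branch: input, conv, pool or dense.

    ``kernel_channels`` is set only on a convolution that spans the full
    channel axis (the branch-initial ``40 x 1 x 3`` kernel); later convs
    operate on a single feature map and leave it at 1.
    """

    kind: Literal["input", "conv", "pool", "dense"]
    kernel_channels: int = 1
    kernel_width: int = 1
    stride: int = 1
    units: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("input", "conv", "pool", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel_width < 1 or self.stride < 1 or self.kernel_channels < 1:
            raise ValueError("kernel_width, stride and kernel_channels must be >= 1")
        if self.kind == "dense" and self.units < 1:
            raise ValueError("dense layers need units >= 1")


@dataclass(frozen=True)
class ShapeTrace:
    """Ordered (layer index, output length, output channels) triples."""

    entries: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    @property
    def lengths(self) -> list[int]:
        return [length for _, length, _ in self.entries]

    @property
    def final_length(self) -> int:
        return self.entries[-1][1]

    def as_rows(self) -> list[dict[str, int]]:
        """Plain tabular form mirroring a 'Output Size' column."""
        return [
            {"layer": idx, "length": length, "channels": chans}
            for idx, length, chans in self.entries
        ]


def conv_output_length(n_in: int, kernel_width: int, stride: int = 1) -> int:
    """Output length of a valid (unpadded) convolution.

    ``floor((n_in - kernel_width) / stride) + 1``; e.g. a width-3 kernel on
    8064 samples yields 8062.
    """
    if kernel_width < 1 or stride < 1:
        raise ValueError("kernel_width and stride must be >= 1")
    if n_in < kernel_width:
        raise InvalidGeometryError(
            f"input length {n_in} shorter than kernel width {kernel_width}"
        )
    return (n_in - kernel_width) // stride + 1


def pool_output_length(n_in: int) -> int:
    """Output length of the window-2, stride-2 max pool, trailing block kept.

    Equivalent to tiling ``[0, n_in)`` into blocks of 2 and counting blocks
    including a final partial one: ``ceil(n_in / 2)``.
    """
    if n_in < 2:
        raise InvalidGeometryError(f"cannot pool length {n_in} (< 2)")
    return -(-n_in // 2)


def trace_branch(
    layers: Iterable[LayerSpec], input_length: int, input_channels: int
) -> ShapeTrace:
    """Propagate (length, channels) through a branch, layer by layer.

    The first conv whose ``kernel_channels`` equals the current channel
    count collapses the channel axis to 1.  Dense layers replace the shape
    with ``(units, 1)``.  Geometry failures carry the offending layer index.
    """
    if input_length < 1 or input_channels < 1:
        raise InvalidGeometryError("input length and channels must be >= 1")
    layers = list(layers)
    length, channels = input_length, input_channels
    entries: list[tuple[int, int, int]] = []
    seen_dense = False
    for idx, layer in enumerate(layers):
        if layer.kind == "input":
            if idx != 0:
                raise InvalidGeometryError(f"layer {idx}: input layer must come first")
            entries.append((idx, length, channels))
            continue
        if layer.kind in ("conv", "pool") and seen_dense:
            raise InvalidGeometryError(
                f"layer {idx}: conv/pool layers must precede dense layers"
            )
        try:
            if layer.kind == "conv":
                length = conv_output_length(length, layer.kernel_width, layer.stride)
                if layer.kernel_channels == channels:
                    channels = 1
                elif layer.kernel_channels != 1:
                    raise InvalidGeometryError(
                        f"conv kernel spans {layer.kernel_channels} channels "
                        f"but input has {channels}"
                    )
            elif layer.kind == "pool":
                length = pool_output_length(length)
            else:  # dense
                seen_dense = True
                length, channels = layer.units, 1
        except InvalidGeometryError as err:
            raise InvalidGeometryError(f"layer {idx}: {err}") from err
        entries.append((idx, length, channels))
    if not entries or entries[0][0] != 0 or layers[0].kind != "input":
        # No explicit input layer: prepend the raw input shape.
        entries = [(0, input_length, input_channels)] + [
            (i + 1, ln, ch) for i, (_, ln, ch) in enumerate(entries)
        ]
    return ShapeTrace(tuple(entries))


def _branch(n_conv_pool_pairs: int, input_channels: int = 40, units: int = 100,
            n_classes: int = 9) -> list[LayerSpec]:
    layers = [LayerSpec("input")]
    for i in range(n_conv_pool_pairs):
        layers.append(
            LayerSpec("conv", kernel_channels=input_channels if i == 0 else 1,
                      kernel_width=3, stride=1)
        )
        layers.append(LayerSpec("pool", kernel_width=2, stride=2))
    layers.append(LayerSpec("dense", units=units))
    layers.append(LayerSpec("dense", units=n_classes))
    return layers


def bottom_branch_spec(input_channels: int = 40, units: int = 100, n_classes: int = 9) -> list[LayerSpec]:
    """One conv/pool pair, then dense 100 and dense 9 (bottom-feature branch)."""
    return _branch(1, input_channels, units, n_classes)


def middle_branch_spec(input_channels: int = 40, units: int = 100, n_classes: int = 9) -> list[LayerSpec]:
    """Two conv/pool pairs (middle-feature branch)."""
    return _branch(2, input_channels, units, n_classes)


def top_branch_spec(input_channels: int = 40, units: int = 100, n_classes: int = 9) -> list[LayerSpec]:
    """Three conv/pool pairs (top-feature branch)."""
    return _branch(3, input_channels, units, n_classes)


def default_branch_specs(input_channels: int = 40, units: int = 100, n_classes: int = 9):
    """(bottom, middle, top) branch layer lists for the default architecture."""
    return (
        bottom_branch_spec(input_channels, units, n_classes),
        middle_branch_spec(input_channels, units, n_classes),
        top_branch_spec(input_channels, units, n_classes),
    )
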