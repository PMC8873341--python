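"""Compact feed-forward CNN: architecture description and shape arithmetic.

The network topology is fixed to conv - conv - maxpool - flatten - dense -
output.  Every inter-layer size follows the sliding-filter relation

    output_size = (N - F) / stride + 1

which must be a positive integer on both spatial axes; ``validate_spec``
propagates it layer by layer and fails fast on any fractional shape.
Parameter counts are reported in two conventions: ``standard`` counts the
input depth of each filter (W*H*depth*K + K, what a real build allocates),
while ``paper`` names the depth-free W*H*K + K form sometimes printed in
compact architecture summaries.

Epoched fNIRS examples (channels x chromophores x window samples) map onto
the network as a 2-D image of channels x samples with the two chromophores
as input depth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ShapeError, ValidationError
from ._network import Network

#: Canonical layer order; freezing presets refer to these group names.
PARAM_GROUPS: tuple[str, ...] = ("conv1", "conv2", "dense", "output")


def conv_output_size(n: int, f: int, stride: int = 1) -> int:
    """Output size of a filter of size ``f`` slid over ``n`` inputs with ``stride``.

    Rejects configurations where the filter does not tile the input exactly
    (``(n - f) % stride != 0``) instead of silently truncating.
    """
    if f < 1 or stride < 1:
        raise ShapeError(f"filter size and stride must be >= 1 (got F={f}, stride={stride})")
    if f > n:
        raise ShapeError(f"filter size {f} exceeds input size {n}")
    if (n - f) % stride != 0:
        raise ShapeError(f"(N - F) = {n - f} not divisible by stride {stride}")
    return (n - f) // stride + 1


def layer_param_count(w: int, h: int, k: int, input_depth: int = 1, mode: str = "standard") -> int:
    """Learnable-parameter count of a conv layer with K filters of size W x H.

    ``standard`` includes the input depth each filter spans; ``paper``
    names the depth-free convention W*H*K + K.
    """
    if min(w, h, k, input_depth) < 1:
        raise ValidationError("all counts must be >= 1")
    if mode == "paper":
        return w * h * k + k
    if mode == "standard":
        return w * h * input_depth * k + k
    raise ValidationError(f"mode must be 'paper' or 'standard', got {mode!r}")


@dataclass(frozen=True)
class LayerSpec:
    """One layer: conv/maxpool/flatten/dense/output with its hyperparameters."""

    kind: str  # conv | maxpool | flatten | dense | output
    filters: int | None = None  # K, conv only
    size: tuple[int, int] | None = None  # (Fh, Fw), conv/pool
    stride: tuple[int, int] | None = None  # conv/pool
    units: int | None = None  # dense/output
    activation: str = "relu"

    def __post_init__(self):
        if self.kind in ("conv", "maxpool"):
            if self.size is None or min(self.size) < 1:
                raise ValidationError(f"{self.kind} layer needs a positive filter size")
            if self.stride is not None and min(self.stride) < 1:
                raise ValidationError("stride must be >= 1")
            if self.kind == "conv" and (self.filters is None or self.filters < 1):
                raise ValidationError("conv layer needs K >= 1 filters")
        elif self.kind in ("dense", "output"):
            if self.units is None or self.units < 1:
                raise ValidationError(f"{self.kind} layer needs units >= 1")
        elif self.kind != "flatten":
            raise ValidationError(f"unknown layer kind {self.kind!r}")


_CANONICAL_TOPOLOGY = ("conv", "conv", "maxpool", "flatten", "dense", "output")


@dataclass(frozen=True)
class CnnSpec:
    """Ordered layer list plus the input geometry it will be applied to.

    ``input_shape`` is (channels, chromophores, window_samples); internally
    the map is channels x samples with chromophores as depth.
    """

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]
    n_classes: int = 3
    allow_custom_topology: bool = False

    def __post_init__(self):
        kinds = tuple(l.kind for l in self.layers)
        if not self.allow_custom_topology and kinds != _CANONICAL_TOPOLOGY:
            raise ValidationError(
                f"topology must be {_CANONICAL_TOPOLOGY} unless allow_custom_topology is set; got {kinds}"
            )
        if self.layers[-1].kind == "output" and self.layers[-1].units != self.n_classes:
            raise ValidationError("output layer units must equal n_classes")

    @classmethod
    def default(cls, input_shape=(36, 2, 100), n_classes: int = 3) -> "CnnSpec":
        """Full-size architecture: 16 and 32 filters of 3x5, 2x2 pool, 64 dense."""
        return cls(
            layers=(
                LayerSpec("conv", filters=16, size=(3, 5), stride=(1, 1)),
                LayerSpec("conv", filters=32, size=(3, 5), stride=(1, 1)),
                LayerSpec("maxpool", size=(2, 2), stride=(2, 2)),
                LayerSpec("flatten"),
                LayerSpec("dense", units=64),
                LayerSpec("output", units=n_classes, activation="softmax"),
            ),
            input_shape=tuple(input_shape),
            n_classes=n_classes,
        )

    @classmethod
    def reduced(cls, input_shape=(36, 2, 100), n_classes: int = 3) -> "CnnSpec":
        """Reduced architecture (strided first conv, 8/16 filters, 32 dense).

        Same topology as :meth:`default` at a fraction of the compute;
        used for cohort-scale experiments and sweeps.
        """
        return cls(
            layers=(
                LayerSpec("conv", filters=8, size=(4, 10), stride=(2, 5)),
                LayerSpec("conv", filters=16, size=(2, 4), stride=(1, 1)),
                LayerSpec("maxpool", size=(2, 2), stride=(2, 2)),
                LayerSpec("flatten"),
                LayerSpec("dense", units=32),
                LayerSpec("output", units=n_classes, activation="softmax"),
            ),
            input_shape=tuple(input_shape),
            n_classes=n_classes,
        )

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "layers": [asdict(l) for l in self.layers],
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "allow_custom_topology": self.allow_custom_topology,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CnnSpec":
        doc = json.loads(text)
        layers = tuple(
            LayerSpec(
                kind=l["kind"],
                filters=l.get("filters"),
                size=tuple(l["size"]) if l.get("size") else None,
                stride=tuple(l["stride"]) if l.get("stride") else None,
                units=l.get("units"),
                activation=l.get("activation", "relu"),
            )
            for l in doc["layers"]
        )
        return cls(
            layers=layers,
            input_shape=tuple(doc["input_shape"]),
            n_classes=doc["n_classes"],
            allow_custom_topology=doc.get("allow_custom_topology", False),
        )


@dataclass
class ShapeReport:
    """Per-layer output shapes and parameter counts from spec validation."""

    rows: list[dict] = field(default_factory=list)

    @property
    def total_params_standard(self) -> int:
        return sum(r["params_standard"] for r in self.rows)

    @property
    def total_params_paper(self) -> int:
        return sum(r["params_paper"] for r in self.rows)

    def __str__(self) -> str:
        lines = [f"{'layer':<10}{'output shape':<20}{'params':>10}"]
        for r in self.rows:
            lines.append(f"{r['name']:<10}{str(r['output_shape']):<20}{r['params_standard']:>10}")
        lines.append(f"{'total':<30}{self.total_params_standard:>10}")
        return "\n".join(lines)


def validate_spec(spec: CnnSpec, input_shape: tuple[int, int, int] | None = None) -> ShapeReport:
    """Propagate shapes through the network and count parameters per layer.

    Raises :class:`ShapeError` (carrying the offending layer index) as soon
    as any axis size becomes fractional or non-positive.
    """
    channels, depth, samples = input_shape or spec.input_shape
    h, w, d = channels, samples, depth  # map height x width x depth
    report = ShapeReport()
    conv_i = dense_in = 0
    for idx, layer in enumerate(spec.layers):
        try:
            if layer.kind == "conv":
                stride = layer.stride or (1, 1)
                h2 = conv_output_size(h, layer.size[0], stride[0])
                w2 = conv_output_size(w, layer.size[1], stride[1])
                conv_i += 1
                report.rows.append(
                    {
                        "name": f"conv{conv_i}",
                        "output_shape": (h2, w2, layer.filters),
                        "params_standard": layer_param_count(
                            layer.size[0], layer.size[1], layer.filters, d, "standard"
                        ),
                        "params_paper": layer_param_count(
                            layer.size[0], layer.size[1], layer.filters, d, "paper"
                        ),
                    }
                )
                h, w, d = h2, w2, layer.filters
            elif layer.kind == "maxpool":
                stride = layer.stride or layer.size
                h2 = conv_output_size(h, layer.size[0], stride[0])
                w2 = conv_output_size(w, layer.size[1], stride[1])
                report.rows.append(
                    {"name": "maxpool", "output_shape": (h2, w2, d), "params_standard": 0, "params_paper": 0}
                )
                h, w = h2, w2
            elif layer.kind == "flatten":
                dense_in = h * w * d
                report.rows.append(
                    {"name": "flatten", "output_shape": (dense_in,), "params_standard": 0, "params_paper": 0}
                )
            elif layer.kind in ("dense", "output"):
                n_params = dense_in * layer.units + layer.units
                report.rows.append(
                    {
                        "name": layer.kind,
                        "output_shape": (layer.units,),
                        "params_standard": n_params,
                        "params_paper": n_params,
                    }
                )
                dense_in = layer.units
        except ShapeError as exc:
            raise ShapeError(f"layer {idx} ({layer.kind}): {exc}", layer_index=idx) from None
    return report


def build_network(spec: CnnSpec, rng_seed: int = 0, dtype=np.float32) -> Network:
    """Instantiate a trainable network for ``spec`` with seeded initialization.

    The handle exposes named parameter groups (conv1, conv2, dense, output)
    for freezing and transfer, forward prediction, and mini-batch training.
    ``dtype`` is the compute precision (float32 by default; float64 for
    gradient-level verification).
    """
    validate_spec(spec)
    return Network(spec, rng_seed=rng_seed, dtype=dtype)
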