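"""Encoder-decoder hotspot detector.

Maps a differential scattered-field tensor (n_ant x n_ant x 2*n_freq, real
and imaginary channels interleaved per frequency) to a probability image on
the phantom grid.  The architecture obeys a fixed set of structural
constraints: size-preserving zero-padded convolutions in the encoder, one
x2 nearest-neighbor upsampling bridge, size-growing unpadded transposed
convolutions in the decoder, ReLU + batch normalization on every hidden
layer, a 1x1 sigmoid convolution at the output, and no pooling anywhere.
The per-block filter counts are this package's realization of that scheme
and are fully configurable through :class:`ArchitectureSpec`.

The spatial-size arithmetic of a spec is validated at build time: the trace
from the input size must end exactly at the label-grid size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn_core import BatchNorm2D, Conv2D, ReLU, Sigmoid, TransposedConv2D, Upsample2x

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "default_architecture",
    "decoder_kernels",
    "Network",
    "build_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # "conv" | "tconv" | "upsample" | "output"
    filters: int = 0
    kernel: int = 0
    repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "tconv", "upsample", "output"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "tconv") and (self.filters < 1 or self.kernel < 1):
            raise ValueError("conv/tconv layers need positive filters and kernel")
        if self.repeat < 1:
            raise ValueError("repeat must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    in_channels: int
    in_size: int
    out_size: int
    layers: tuple[LayerSpec, ...]

    def size_trace(self) -> list[int]:
        """Spatial size after each block; raises if it misses ``out_size``."""
        s = self.in_size
        trace = [s]
        for i, layer in enumerate(self.layers):
            for _ in range(layer.repeat):
                if layer.kind == "conv" or layer.kind == "output":
                    pass  # size-preserving
                elif layer.kind == "upsample":
                    s *= 2
                elif layer.kind == "tconv":
                    s += layer.kernel - 1
                trace.append(s)
            if s > self.out_size:
                raise ValueError(
                    f"layer {i} ({layer.kind}) overshoots the output size: "
                    f"trace {trace} vs target {self.out_size}"
                )
        if s != self.out_size:
            raise ValueError(
                f"architecture ends at {s}x{s}, not {self.out_size}x{self.out_size}; "
                f"size trace {trace}"
            )
        if not self.layers or self.layers[-1].kind != "output":
            raise ValueError("architecture must end with an output layer")
        return trace


def decoder_kernels(start: int, target: int, n_layers: int) -> list[int]:
    """Kernel sizes for ``n_layers`` unpadded transposed convs growing
    ``start`` -> ``target`` as evenly as possible (each kernel >= 2)."""
    grow = target - start
    if grow < n_layers:
        raise ValueError("not enough growth for that many transposed-conv layers")
    base, extra = divmod(grow, n_layers)
    return [base + 1 + (1 if i < extra else 0) for i in range(n_layers)]


def default_architecture(
    in_channels: int = 32,
    in_size: int = 16,
    out_size: int = 50,
    width: int = 64,
) -> ArchitectureSpec:
    """Reference realization of the encoder-decoder scheme.

    At the full problem scale (in 16x16x32, out 50x50, width 64) this is:
    encoder convs 64/128/256 (kernel 3, each x2), upsample 16->32, decoder
    transposed convs 256/128/64/32/16 with kernels 5,5,5,4,4 (32->50), 1x1
    sigmoid output.  ``width`` scales every filter count for smaller
    problems.
    """
    up_size = in_size * 2
    kernels = decoder_kernels(up_size, out_size, 5)
    w = width
    layers = (
        LayerSpec("conv", w, 3, repeat=2),
        LayerSpec("conv", 2 * w, 3, repeat=2),
        LayerSpec("conv", 4 * w, 3, repeat=2),
        LayerSpec("upsample"),
        LayerSpec("tconv", 4 * w, kernels[0]),
        LayerSpec("tconv", 2 * w, kernels[1]),
        LayerSpec("tconv", w, kernels[2]),
        LayerSpec("tconv", max(w // 2, 4), kernels[3]),
        LayerSpec("tconv", max(w // 4, 4), kernels[4]),
        LayerSpec("output"),
    )
    return ArchitectureSpec(in_channels, in_size, out_size, layers)


class Network:
    """A built encoder-decoder; parameters live in the layer objects."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator, dtype=np.float32):
        spec.size_trace()
        self.spec = spec
        self.dtype = dtype
        self.layers: list = []
        c = spec.in_channels
        for layer in spec.layers:
            for _ in range(layer.repeat):
                if layer.kind == "conv":
                    self.layers += [
                        Conv2D(c, layer.filters, layer.kernel, rng, dtype),
                        BatchNorm2D(layer.filters, dtype),
                        ReLU(),
                    ]
                    c = layer.filters
                elif layer.kind == "tconv":
                    self.layers += [
                        TransposedConv2D(c, layer.filters, layer.kernel, rng, dtype),
                        BatchNorm2D(layer.filters, dtype),
                        ReLU(),
                    ]
                    c = layer.filters
                elif layer.kind == "upsample":
                    self.layers.append(Upsample2x())
                elif layer.kind == "output":
                    self.layers += [Conv2D(c, 1, 1, rng, dtype), Sigmoid()]
                    c = 1

    # -- passes ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability maps (N, out, out) for input tensors (N, C, s, s)."""
        h = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0]

    def backward_from_bce(self, probs: np.ndarray, targets: np.ndarray) -> None:
        """Backpropagate the mean binary cross-entropy loss.

        Uses the fused sigmoid/BCE gradient (probs - targets)/m at the
        logits, skipping the sigmoid layer's own backward for stability.
        """
        m = probs.size
        dy = ((probs - targets.astype(self.dtype)) / m)[:, None, :, :].astype(self.dtype)
        for layer in reversed(self.layers[:-1]):  # last layer is the Sigmoid
            dy = layer.backward(dy)

    def parameters(self):
        """Yield (unique_name, layer, param_name) triples."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{i}.{name}", layer, name


def build_model(
    spec: ArchitectureSpec, seed: int = 0, dtype=np.float32
) -> Network:
    """Validate the spec's size arithmetic and instantiate the network."""
    return Network(spec, np.random.default_rng(seed), dtype)


def bce_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    t = targets
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def predict(
    model: Network, tensors: np.ndarray, alpha_dec: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Binary hotspot images and probability maps for a batch of inputs.

    ``tensors`` is (N, s, s, 2*n_freq) in measurement layout or already
    (N, C, s, s); the decision rule is probability > alpha_dec (default 0.5).
    """
    if not 0.0 < alpha_dec < 1.0:
        raise ValueError("alpha_dec must be in (0, 1)")
    x = np.asarray(tensors)
    if x.ndim == 3:
        x = x[None]
    if x.shape[-1] == self_channels(model) and x.shape[1] != self_channels(model):
        x = np.moveaxis(x, -1, 1)
    probs = model.forward(x, train=False)
    return probs > alpha_dec, probs


def self_channels(model: Network) -> int:
    return model.spec.in_channels


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(path, model: Network, extra: dict | None = None) -> None:
    spec = model.spec
    meta = {
        "in_channels": spec.in_channels,
        "in_size": spec.in_size,
        "out_size": spec.out_size,
        "layers": [vars(l) for l in spec.layers],
        "extra": extra or {},
    }
    arrays = {}
    for i, layer in enumerate(model.layers):
        for name, value in layer.params.items():
            arrays[f"layer{i}.{name}"] = value
        if isinstance(layer, BatchNorm2D):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Network, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = ArchitectureSpec(
            meta["in_channels"],
            meta["in_size"],
            meta["out_size"],
            tuple(LayerSpec(**l) for l in meta["layers"]),
        )
        model = build_model(spec)
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = data[f"layer{i}.running_mean"]
                layer.running_var = data[f"layer{i}.running_var"]
    return model, meta["extra"]
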