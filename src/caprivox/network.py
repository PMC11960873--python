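"""The VGG-style convolutional classifier for log-Mel spectrograms.

Four blocks of two 3x3 convolutions (64, 128, 256, 512 nominal filters)
each followed by 2x2 max pooling, then two 4096-unit fully connected
layers, dropout, and an 8-way softmax output.  A width multiplier scales
the conv-filter and dense-unit counts jointly so the same architecture can
be exercised at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .audio import LogMelSpectrogram
from .classes import CLASSES

__all__ = ["ArchitectureSpec", "Network", "build", "forward", "embed",
           "parameter_count", "save_network", "load_network"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural hyperparameters of the classifier."""

    block_filters: tuple[int, ...] = (64, 128, 256, 512)
    convs_per_block: int = 2
    kernel: int = 3
    dense_units: int = 4096
    n_dense: int = 2
    dropout_rate: float = 0.5
    n_classes: int = 8
    input_shape: tuple[int, int, int] = (128, 44, 1)
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.n_classes != len(CLASSES):
            raise ValueError(f"n_classes must equal |D| = {len(CLASSES)}")
        h, w = self.input_shape[:2]
        if (h >> len(self.block_filters)) < 1 or (w >> len(self.block_filters)) < 1:
            raise ValueError("input too small to survive the pooling stages")

    def effective_filters(self, nominal: int) -> int:
        return max(1, round(self.width_multiplier * nominal))

    @property
    def effective_dense(self) -> int:
        return max(1, round(self.width_multiplier * self.dense_units))

    @property
    def pooled_shape(self) -> tuple[int, int]:
        h, w = self.input_shape[:2]
        for _ in self.block_filters:
            h, w = h // 2, w // 2
        return h, w

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["block_filters"] = tuple(d["block_filters"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass
class Network:
    """An ordered list of named layers plus inference metadata.

    ``norm`` is the (mean, std) affine applied to spectrograms before the
    first layer; it is fitted on training data and stored with the network
    so inference is self-contained.
    """

    layers: list[tuple[str, nn.Layer]]
    spec: ArchitectureSpec | None = None
    norm: tuple[float, float] = (0.0, 1.0)
    classes: tuple[str, ...] = CLASSES
    meta: dict = field(default_factory=dict)

    def layer(self, name: str) -> nn.Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def layer_names(self) -> list[str]:
        return [n for n, _ in self.layers]

    @property
    def channel_layers(self) -> list[str]:
        """Names of layers with a channel axis (conv and dense)."""
        return [n for n, l in self.layers if isinstance(l, (nn.Conv2D, nn.Dense))]

    def normalize(self, x: np.ndarray) -> np.ndarray:
        mean, std = self.norm
        return ((x - mean) / std).astype(np.float32)

    def forward_raw(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a normalized NCHW batch; activations stay cached."""
        h = x
        for _, layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i][1]
            if i == 0 and isinstance(layer, nn.Conv2D):
                return layer.backward(grad, need_input_grad=False)
            grad = layer.backward(grad)
        return grad

    @property
    def n_parameters(self) -> int:
        return sum(int(p.size) for _, l in self.layers for p in l.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for _, l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for _, l in self.layers:
            for p in l.params:
                p[...] = weights[i]
                i += 1


def build(spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0) -> Network:
    """Instantiate the architecture with seed-deterministic He initialization."""
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Layer]] = []
    in_ch = spec.input_shape[2]
    for bi, nominal in enumerate(spec.block_filters, start=1):
        out_ch = spec.effective_filters(nominal)
        for ci in range(1, spec.convs_per_block + 1):
            layers.append((f"block_{bi}/conv_{ci}",
                           nn.Conv2D(in_ch, out_ch, k=spec.kernel, relu=True, rng=rng)))
            in_ch = out_ch
        layers.append((f"pool_{bi}", nn.MaxPool2x2()))
    layers.append(("flatten", nn.Flatten()))
    h, w = spec.pooled_shape
    n_in = h * w * in_ch
    for di in range(1, spec.n_dense + 1):
        layers.append((f"fc_{di}", nn.Dense(n_in, spec.effective_dense, relu=True, rng=rng)))
        n_in = spec.effective_dense
    layers.append(("dropout", nn.Dropout(spec.dropout_rate, rng=np.random.default_rng(seed + 1))))
    layers.append(("output", nn.Dense(n_in, spec.n_classes, relu=False, rng=rng)))
    return Network(layers=layers, spec=spec)


def parameter_count(spec: ArchitectureSpec) -> int:
    """Closed-form parameter count implied by the spec."""
    total = 0
    in_ch = spec.input_shape[2]
    for nominal in spec.block_filters:
        out_ch = spec.effective_filters(nominal)
        for _ in range(spec.convs_per_block):
            total += out_ch * in_ch * spec.kernel**2 + out_ch
            in_ch = out_ch
    h, w = spec.pooled_shape
    n_in = h * w * in_ch
    for _ in range(spec.n_dense):
        total += n_in * spec.effective_dense + spec.effective_dense
        n_in = spec.effective_dense
    total += n_in * spec.n_classes + spec.n_classes
    return total


def _as_batch(batch, net: Network) -> np.ndarray:
    if isinstance(batch, LogMelSpectrogram):
        batch = [batch]
    if isinstance(batch, np.ndarray):
        if batch.ndim == 4:
            x = batch  # NHWC
        elif net.spec is None:
            x = batch if batch.ndim == 2 else batch[np.newaxis, :]  # raw dense input
        elif batch.ndim == 2:
            x = batch[np.newaxis, :, :, np.newaxis]  # one spectrogram matrix
        else:
            x = batch[:, :, :, np.newaxis]  # batch of spectrogram matrices
    else:
        arrays = [b.values if isinstance(b, LogMelSpectrogram) else np.asarray(b) for b in batch]
        x = np.stack(arrays)[:, :, :, np.newaxis]
    expected = net.spec.input_shape if net.spec else None
    if expected is not None and x.shape[1:3] != tuple(expected[:2]):
        raise ValueError(f"spectrogram shape {x.shape[1:3]} != expected {tuple(expected[:2])}")
    return net.normalize(x)


def forward(net: Network, batch) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) in inference mode."""
    logits = net.forward_raw(_as_batch(batch, net), train=False)
    return nn.softmax(logits)


def embed(net: Network, spectrogram) -> np.ndarray:
    """Post-ReLU activation of the last fully connected hidden layer."""
    net.forward_raw(_as_batch(spectrogram, net), train=False)
    fc_names = [n for n in net.layer_names() if n.startswith("fc_")]
    out = net.layer(fc_names[-1]).last_output
    return out[0] if out.shape[0] == 1 else out


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON metadata


def save_network(net: Network, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for name, layer in net.layers:
        for i, p in enumerate(layer.params):
            arrays[f"{name}::{i}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "spec": net.spec.to_dict() if net.spec else None,
        "norm": list(net.norm),
        "classes": list(net.classes),
        "meta": net.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_network(path: str | Path) -> Network:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ArchitectureSpec.from_dict(meta["spec"]) if meta["spec"] else None
    net = build(spec) if spec else None
    if net is None:
        raise ValueError("checkpoint has no architecture spec; cannot rebuild")
    with np.load(path.with_suffix(".npz")) as data:
        for name, layer in net.layers:
            for i in range(len(layer.params)):
                layer.params[i][...] = data[f"{name}::{i}"]
    net.norm = tuple(meta["norm"])
    net.classes = tuple(meta["classes"])
    net.meta = meta.get("meta", {})
    return net
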