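"""Conditional relevance propagation and heatmap aggregation.

Layer-wise relevance propagation (LRP) decomposes a network's pre-softmax
score for a target class into per-input relevance scores by propagating
the score backwards with layer-specific rules.  Concept relevance
propagation (CRP) extends this with *conditions*: per-layer channel
subsets outside of which relevance is zeroed during the backward pass,
yielding channel-specific (concept-specific) heatmaps.

Rule assignment follows the standard composite for VGG-style networks:
alpha1-beta0 (z+) for convolutions, epsilon for dense layers, winner
routing through max pooling, shape-preserving pass-through for flatten
and (inference-mode) dropout.  Because every rule distributes relevance
with coefficients that depend only on the forward activations, the
backward map is linear in the relevance itself — which is exactly why the
singleton-channel conditional heatmaps of a layer sum to the
unconditional heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .audio import LogMelSpectrogram
from .network import Network, _as_batch

__all__ = ["ConditionSet", "RelevanceBundle", "ChannelRanking", "ClassHeatmapSpec",
           "ClassHeatmap", "relevance", "rank_channels", "sample_report",
           "select_central", "class_average_heatmap"]

_EPS = 1e-6


@dataclass(frozen=True)
class ConditionSet:
    """Mapping layer name -> allowed channel indices; empty = unconditional."""

    conditions: tuple[tuple[str, tuple[int, ...]], ...] = ()

    @classmethod
    def from_dict(cls, d: dict[str, object]) -> "ConditionSet":
        items = []
        for name, chans in d.items():
            items.append((name, tuple(sorted(int(c) for c in np.atleast_1d(list(chans))))))
        return cls(conditions=tuple(items))

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return dict(self.conditions)

    def validate(self, net: Network) -> None:
        names = set(net.layer_names())
        for name, chans in self.conditions:
            if name not in names:
                raise ValueError(f"condition references unknown layer {name!r}")
            layer = net.layer(name)
            width = getattr(layer, "n_channels", None)
            if width is None:
                raise ValueError(f"layer {name!r} has no channel axis")
            if chans and (min(chans) < 0 or max(chans) >= width):
                raise ValueError(f"condition channels {chans} out of range for {name!r} (width {width})")


@dataclass
class RelevanceBundle:
    """Relevance tensors from one backward pass.

    ``layer_relevance`` maps layer name -> relevance at that layer's output
    (same shape as the activation, minus the batch axis); ``heatmap`` is the
    input-plane relevance (n_mels x n_frames).
    """

    target: int
    layer_relevance: dict[str, np.ndarray]
    heatmap: np.ndarray
    conditions: ConditionSet
    rules: dict[str, str]
    score: float  # pre-softmax score of the target class

    def positive_heatmap(self) -> np.ndarray:
        return np.maximum(self.heatmap, 0.0)


@dataclass
class ChannelRanking:
    """Per-channel total relevance at one layer, sorted descending."""

    layer: str
    ranking: list[tuple[int, float]]

    @property
    def channels(self) -> list[int]:
        return [c for c, _ in self.ranking]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.ranking]


@dataclass(frozen=True)
class ClassHeatmapSpec:
    """Bookkeeping for class-wise average heatmaps.

    ``m_bar = dictionary_size * n_spectrograms * g_channels`` is recorded as
    the nominal heatmap-count formula; the actually aggregated count also
    depends on the number of analyzed layers and is reported separately.
    """

    dictionary_size: int = 8
    n_spectrograms: int = 100
    g_channels: int = 20

    @property
    def m_bar(self) -> int:
        return self.dictionary_size * self.n_spectrograms * self.g_channels


@dataclass
class ClassHeatmap:
    class_id: str
    heatmap: np.ndarray
    n_contributors: int
    spec: ClassHeatmapSpec = field(default_factory=ClassHeatmapSpec)


# ---------------------------------------------------------------------------
# relevance propagation


def _stabilize(z: np.ndarray, eps: float = _EPS) -> np.ndarray:
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def _dense_epsilon(layer: nn.Dense, R: np.ndarray) -> np.ndarray:
    x = layer.last_input
    z = x @ layer.W + layer.b
    s = R / _stabilize(z)
    return x * (s @ layer.W.T)


def _conv_alpha1beta0(layer: nn.Conv2D, R: np.ndarray) -> np.ndarray:
    x = layer.last_input
    xp, xn = np.maximum(x, 0.0), np.minimum(x, 0.0)
    Wp, Wn = np.maximum(layer.W, 0.0), np.minimum(layer.W, 0.0)
    zp = nn.conv2d(xp, Wp) + nn.conv2d(xn, Wn)
    s = R / _stabilize(zp)
    return xp * nn.conv2d_transpose(s, Wp) + xn * nn.conv2d_transpose(s, Wn)


def _apply_condition(R: np.ndarray, allowed: tuple[int, ...]) -> np.ndarray:
    """Zero relevance outside the allowed channels (channel axis = last)."""
    mask = np.zeros(R.shape[-1], dtype=R.dtype)
    mask[list(allowed)] = 1.0
    return R * mask


def relevance(
    net: Network,
    x: LogMelSpectrogram | np.ndarray,
    target: int,
    conditions: ConditionSet | dict | None = None,
) -> RelevanceBundle:
    """Backward relevance pass for one input and one target class.

    Relevance is seeded at the output layer with the target's pre-softmax
    score; at every layer carrying a condition, relevance outside the
    allowed channel subset is zeroed before propagating through the layer.
    """
    if conditions is None:
        conditions = ConditionSet()
    elif isinstance(conditions, dict):
        conditions = ConditionSet.from_dict(conditions)
    conditions.validate(net)
    cond = conditions.as_dict()

    xb = _as_batch(x, net)
    logits = net.forward_raw(xb, train=False)
    score = float(logits[0, target])

    R = np.zeros_like(logits)
    R[0, target] = score
    layer_rel: dict[str, np.ndarray] = {}
    rules: dict[str, str] = {}
    for i in reversed(range(len(net.layers))):
        name, layer = net.layers[i]
        layer_rel[name] = R[0].copy()
        if name in cond:
            R = _apply_condition(R, cond[name])
        if isinstance(layer, nn.Dense):
            R = _dense_epsilon(layer, R)
            rules[name] = "epsilon"
        elif isinstance(layer, nn.Conv2D):
            R = _conv_alpha1beta0(layer, R)
            rules[name] = "alpha1beta0"
        elif isinstance(layer, nn.MaxPool2x2):
            R = layer.route(R)
            rules[name] = "winner"
        elif isinstance(layer, nn.Flatten):
            R = layer.backward(R)
            rules[name] = "reshape"
        elif isinstance(layer, nn.Dropout):
            rules[name] = "identity"
        else:  # pragma: no cover - no other layer types exist
            raise TypeError(f"no relevance rule for layer type {type(layer).__name__}")
    heatmap = R[0, :, :, 0] if R.ndim == 4 else R[0]
    if not np.all(np.isfinite(heatmap)):
        raise FloatingPointError("non-finite relevance; check network weights")
    return RelevanceBundle(
        target=int(target),
        layer_relevance=layer_rel,
        heatmap=heatmap,
        conditions=conditions,
        rules=rules,
        score=score,
    )


def rank_channels(
    net: Network,
    x: LogMelSpectrogram | np.ndarray,
    target: int,
    layer: str,
    conditions: ConditionSet | dict | None = None,
) -> ChannelRanking:
    """Channels of ``layer`` ordered by total relevance (descending).

    A channel's score is the sum of the layer's output relevance over all
    its positions; ties break by ascending channel index.
    """
    lobj = net.layer(layer)
    if not hasattr(lobj, "n_channels"):
        raise ValueError(f"layer {layer!r} has no channel axis")
    bundle = relevance(net, x, target, conditions)
    R = bundle.layer_relevance[layer]
    scores = R.sum(axis=tuple(range(R.ndim - 1))) if R.ndim > 1 else R
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranking = [(int(c), float(scores[c])) for c in order]
    return ChannelRanking(layer=layer, ranking=ranking)


def sample_report(
    net: Network,
    x: LogMelSpectrogram | np.ndarray,
    target: int,
    layers: list[str],
    k: int = 6,
) -> dict[str, list[tuple[int, float, np.ndarray]]]:
    """Top-k channel report per layer: (channel, score, conditional heatmap).

    Each heatmap is the input-plane relevance obtained when only that single
    channel of the layer is allowed to pass relevance.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    report: dict[str, list[tuple[int, float, np.ndarray]]] = {}
    for layer in layers:
        width = getattr(net.layer(layer), "n_channels", None)
        if width is None:
            raise ValueError(f"layer {layer!r} has no channel axis")
        if k > width:
            raise ValueError(f"k={k} exceeds width {width} of layer {layer!r}")
        ranking = rank_channels(net, x, target, layer)
        entries = []
        for c, score in ranking.ranking[:k]:
            bundle = relevance(net, x, target, {layer: (c,)})
            entries.append((c, score, bundle.heatmap))
        report[layer] = entries
    return report


# ---------------------------------------------------------------------------
# class-wise aggregation


def select_central(spectrograms: list[LogMelSpectrogram] | np.ndarray, n: int) -> list[int]:
    """Indices of the ``n`` samples closest to the class centroid.

    The centroid of the flattened spectrograms is the k-means solution for
    k=1 under Euclidean distance; ties break by input order.
    """
    X = np.stack([s.values if isinstance(s, LogMelSpectrogram) else np.asarray(s)
                  for s in spectrograms]).reshape(len(spectrograms), -1)
    if n > len(X):
        raise ValueError(f"cannot select {n} of {len(X)} samples")
    centroid = X.mean(axis=0)
    d = np.linalg.norm(X - centroid, axis=1)
    order = np.argsort(d, kind="stable")
    return [int(i) for i in order[:n]]


def class_average_heatmap(
    net: Network,
    spectrograms: list[LogMelSpectrogram] | np.ndarray,
    class_id: str,
    target: int,
    layers: list[str],
    spec: ClassHeatmapSpec = ClassHeatmapSpec(),
) -> ClassHeatmap:
    """Average the top-g conditional heatmaps of the n most central samples.

    For each selected spectrogram and each analyzed layer, the g most
    relevant channels' conditional heatmaps are computed and all collected
    maps are averaged arithmetically.
    """
    chosen = select_central(spectrograms, spec.n_spectrograms)
    acc = None
    count = 0
    for i in chosen:
        x = spectrograms[i]
        rep = sample_report(net, x, target, layers, k=spec.g_channels)
        for entries in rep.values():
            for _, _, hm in entries:
                acc = hm.copy() if acc is None else acc + hm
                count += 1
    if count == 0:
        raise ValueError("no heatmaps aggregated (g=0 or no layers)")
    return ClassHeatmap(class_id=class_id, heatmap=acc / count, n_contributors=count, spec=spec)
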