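"""Interactive explanation answers: influence, retrieval, difference, sonification.

Four question types close the loop between the classifier and the animal
scientist:

1. *Which time-frequency content drove this prediction?* — relevance map,
   thresholded high-relevance region, its extents in seconds and Hz, and a
   sonification of just that region.
2. *Which corpus vocalizations most resemble this one?* — cosine-distance
   retrieval in the network's embedding space.
3. *Which are most different?* — the same ranking, reversed.
4. *How do two vocalizations differ?* — subtraction of their relevance
   maps, with the high-|difference| regions of each clip sonified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .audio import (AudioClip, FrontendConfig, extract_logmel, mel_center_frequencies,
                    mel_filterbank, segment, standardize_duration)
from .explain import relevance
from .network import Network, embed, forward

__all__ = ["RegionMask", "NeighborList", "answer_influence", "sonify_region",
           "find_similar", "find_dissimilar", "relevance_difference", "clip_embedding"]


@dataclass
class RegionMask:
    """Soft mask over the log-Mel plane; values in [0, 1]."""

    values: np.ndarray
    percentile: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("mask values must lie in [0, 1]")


@dataclass
class NeighborList:
    """Ordered (corpus id, cosine distance) retrieval result."""

    query_id: str
    neighbors: list[tuple[str, float]]
    order: str  # "similar" (ascending) or "dissimilar" (descending)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.neighbors]

    @property
    def distances(self) -> list[float]:
        return [d for _, d in self.neighbors]


# ---------------------------------------------------------------------------
# question 1: influence


def _threshold_mask(heatmap: np.ndarray, percentile: float) -> RegionMask:
    """Binary mask of positive-relevance cells at or above the percentile."""
    pos = np.maximum(heatmap, 0.0)
    if not np.any(pos > 0):
        return RegionMask(np.zeros_like(pos), percentile)
    thr = np.percentile(pos[pos > 0], percentile)
    return RegionMask(((pos >= thr) & (pos > 0)).astype(float), percentile)


def _mask_extents(mask: RegionMask, config: FrontendConfig) -> dict:
    """Time (s) and frequency (Hz) bounds of the active mask cells."""
    rows, cols = np.nonzero(mask.values)
    if len(rows) == 0:
        return {"t_start": None, "t_end": None, "f_low": None, "f_high": None}
    centers = mel_center_frequencies(config)
    dt = config.hop_length / config.sample_rate
    return {
        "t_start": float(cols.min() * dt),
        "t_end": float((cols.max() + 1) * dt),
        "f_low": float(centers[rows.min()]),
        "f_high": float(centers[rows.max()]),
    }


def answer_influence(
    net: Network,
    clip: AudioClip,
    config: FrontendConfig = FrontendConfig(),
    percentile: float = 90.0,
) -> dict:
    """Explain the network's own prediction for a clip.

    The clip's class is predicted by mean-softmax aggregation over its
    segments; the relevance map is computed on the segment the network is
    most confident about, thresholded at the ``percentile`` of positive
    relevance, located on the time/frequency axes, and sonified.
    """
    std = standardize_duration(clip, config)
    segs = segment(std, config)
    feats = [extract_logmel(s, config) for s in segs]
    probs = forward(net, feats)
    predicted = int(np.argmax(probs.mean(axis=0)))
    seg_idx = int(np.argmax(probs[:, predicted]))

    bundle = relevance(net, feats[seg_idx], predicted)
    mask = _threshold_mask(bundle.heatmap, percentile)
    extents = _mask_extents(mask, config)
    sonified = sonify_region(segs[seg_idx], mask, config)
    return {
        "predicted_class": net.classes[predicted],
        "probabilities": probs.mean(axis=0),
        "segment_index": seg_idx,
        "heatmap": bundle.heatmap,
        "mask": mask,
        "extents": extents,
        "sonified": sonified,
    }


# ---------------------------------------------------------------------------
# sonification


def sonify_region(seg: AudioClip, mask: RegionMask, config: FrontendConfig = FrontendConfig()) -> AudioClip:
    """Render the masked time-frequency region of a 1-s segment as audio.

    The mel-plane mask is lifted to the linear STFT plane through the
    pseudo-inverse of the mel filterbank (clipped to [0, 1]), multiplied
    into the segment's magnitude STFT, and resynthesized with the original
    phase; output length equals input length.
    """
    if len(seg) != config.segment_samples:
        raise ValueError("sonify_region expects the 1-s segment the mask was computed on")
    win, hop = config.win_length, config.hop_length
    window = np.hanning(win + 1)[:-1]
    x = np.pad(seg.samples.astype(np.float64), win // 2)
    n_frames = 1 + len(seg) // hop
    idx = np.arange(win)[np.newaxis, :] + hop * np.arange(n_frames)[:, np.newaxis]
    S = np.fft.rfft(x[idx] * window, axis=1)  # (frames, bins)

    if mask.values.shape != (config.n_mels, n_frames):
        raise ValueError(
            f"mask shape {mask.values.shape} != ({config.n_mels}, {n_frames})"
        )
    fb = mel_filterbank(config)
    lifted = np.clip(np.linalg.pinv(fb) @ mask.values, 0.0, 1.0)  # (bins, frames)
    S_masked = S * lifted.T

    frames = np.fft.irfft(S_masked, n=win, axis=1) * window
    out = np.zeros(win + hop * (n_frames - 1))
    norm = np.zeros_like(out)
    wsq = window**2
    for i in range(n_frames):
        out[i * hop : i * hop + win] += frames[i]
        norm[i * hop : i * hop + win] += wsq
    out = out / np.maximum(norm, 1e-8)
    out = out[win // 2 : win // 2 + len(seg)]
    return AudioClip(out.astype(np.float32), seg.rate, label=seg.label,
                     source_id=seg.source_id, segment_index=seg.segment_index)


# ---------------------------------------------------------------------------
# questions 2-3: retrieval


def clip_embedding(net: Network, clip: AudioClip, config: FrontendConfig = FrontendConfig()) -> np.ndarray:
    """Mean of the clip's segment embeddings (last hidden dense layer)."""
    std = standardize_duration(clip, config)
    feats = [extract_logmel(s, config) for s in segment(std, config)]
    embs = np.stack([np.asarray(embed(net, f)) for f in feats])
    return embs.mean(axis=0)


def _retrieve(net, clip, corpus, top_k, config, order):
    if not corpus:
        raise ValueError("empty retrieval corpus")
    q = clip_embedding(net, clip, config)[np.newaxis, :]
    ids = [c.source_id for c in corpus]
    E = np.stack([clip_embedding(net, c, config) for c in corpus])
    d = cdist(q, E, metric="cosine")[0]
    d = np.nan_to_num(d, nan=1.0)  # zero embeddings have undefined angle
    sign = 1.0 if order == "similar" else -1.0
    ranked = np.lexsort((np.arange(len(d)), sign * d))
    pairs = [(ids[i], float(d[i])) for i in ranked[:top_k]]
    return NeighborList(query_id=clip.source_id, neighbors=pairs, order=order)


def find_similar(net: Network, clip: AudioClip, corpus: list[AudioClip], top_k: int = 5,
                 config: FrontendConfig = FrontendConfig()) -> NeighborList:
    """Corpus clips closest to the query in embedding cosine distance."""
    return _retrieve(net, clip, corpus, top_k, config, "similar")


def find_dissimilar(net: Network, clip: AudioClip, corpus: list[AudioClip], top_k: int = 5,
                    config: FrontendConfig = FrontendConfig()) -> NeighborList:
    """Corpus clips farthest from the query in embedding cosine distance."""
    return _retrieve(net, clip, corpus, top_k, config, "dissimilar")


# ---------------------------------------------------------------------------
# question 4: difference


def _minmax(h: np.ndarray) -> np.ndarray:
    lo, hi = h.min(), h.max()
    if hi - lo < 1e-12:
        return np.zeros_like(h)
    return (h - lo) / (hi - lo)


def relevance_difference(
    net: Network,
    clip_a: AudioClip,
    clip_b: AudioClip,
    config: FrontendConfig = FrontendConfig(),
    percentile: float = 90.0,
) -> dict:
    """Subtract the two clips' relevance maps and sonify the differing regions.

    Each clip's map is computed for its own predicted class on its most
    confident segment and min-max normalized to [0, 1] before subtraction,
    so clips of different energy are comparable.  The mask selects cells
    whose |difference| exceeds the ``percentile`` of non-zero |difference|.
    """
    answers = [answer_influence(net, c, config, percentile) for c in (clip_a, clip_b)]
    map_a = _minmax(answers[0]["heatmap"])
    map_b = _minmax(answers[1]["heatmap"])
    diff = map_a - map_b
    mag = np.abs(diff)
    if np.any(mag > 0):
        thr = np.percentile(mag[mag > 0], percentile)
        mask = RegionMask(((mag >= thr) & (mag > 0)).astype(float), percentile)
    else:
        mask = RegionMask(np.zeros_like(mag), percentile)

    sonified = []
    for clip, ans in zip((clip_a, clip_b), answers):
        std = standardize_duration(clip, config)
        segs = segment(std, config)
        sonified.append(sonify_region(segs[ans["segment_index"]], mask, config))
    return {
        "difference": diff,
        "mask": mask,
        "sonified": tuple(sonified),
        "predicted_classes": (answers[0]["predicted_class"], answers[1]["predicted_class"]),
    }
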