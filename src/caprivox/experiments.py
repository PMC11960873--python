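"""Reference experiments at desk scale.

The full-width architecture trained on a real corpus is a GPU-scale job;
the desk-scale reference experiment keeps the complete pipeline — synthetic
8-class corpus, full 15-variant augmentation of training folds, stratified
5-fold cross-validation, original-audio evaluation — while scaling the
network width to 0.125 and training for a single epoch, which the cleanly
separable synthetic classes need to converge.
"""

from __future__ import annotations

import numpy as np

from .api import ClassifierResults, GoatCallClassifier
from .classes import CLASSES, class_index
from .explain import relevance
from .network import ArchitectureSpec, forward
from .synthetic import default_specs
from .training import TrainConfig

__all__ = ["desk_scale_crossval", "localization_ratios", "translation_flip_rate"]


def desk_scale_crossval(
    seed: int = 7,
    n_per_class: int = 40,
    width: float = 0.125,
    max_epochs: int = 1,
    k_folds: int = 5,
    verbose: bool = False,
) -> ClassifierResults:
    """Cross-validated training of the width-scaled classifier on synthetic calls.

    Returns the fitted :class:`~caprivox.api.ClassifierResults`; with the
    defaults this takes roughly 10-15 minutes on one CPU core.
    """
    model = GoatCallClassifier.from_synthetic(
        n_per_class,
        seed=seed,
        arch=ArchitectureSpec(width_multiplier=width),
        train_config=TrainConfig(seed=seed, max_epochs=max_epochs, k_folds=k_folds),
    )
    return model.fit(verbose=verbose)


def _fold_of_source(results: ClassifierResults) -> dict[str, int]:
    return {sid: f for f, (_, test) in enumerate(results.plan.folds) for sid in test}


def localization_ratios(results: ClassifierResults, calls_per_class: int = 20) -> dict[str, float]:
    """Heatmap localization against the generator's ground-truth bands.

    For held-out test calls, computes the fraction of positive relevance
    falling inside the call's class-discriminative mel band, divided by the
    band's area fraction of the input plane.  A ratio of 1 means relevance is
    spread indifferently; trained models should concentrate well above 1.
    Each call is explained by the fold network that never saw it.
    """
    frontend = results.model.frontend
    bands = {s.class_id: s.mel_band_indices(frontend) for s in default_specs()}
    fold_of = _fold_of_source(results)
    out: dict[str, float] = {}
    for cls_name in CLASSES:
        target = class_index(cls_name)
        lo, hi = bands[cls_name]
        area_fraction = (hi - lo + 1) / frontend.n_mels
        ratios = []
        for clip in results.model.clips:
            if clip.label != cls_name or len(ratios) >= calls_per_class:
                continue
            net = results.networks[fold_of[clip.source_id]]
            feats = results.cache.original(clip.source_id)
            probs = forward(net, feats)
            seg = int(np.argmax(probs[:, target]))
            heatmap = relevance(net, feats[seg], target).heatmap
            pos = np.maximum(heatmap, 0.0)
            total = pos.sum()
            if total <= 0:
                ratios.append(0.0)
                continue
            in_band = pos[lo : hi + 1, :].sum() / total
            ratios.append(in_band / area_fraction)
        out[cls_name] = float(np.mean(ratios))
    return out


def translation_flip_rate(results: ClassifierResults, hop_samples: int = 512,
                          max_clips: int = 100) -> float:
    """Fraction of held-out segments whose argmax changes under a one-hop shift.

    Measures the pooling-induced translation tolerance: each test clip's
    first 1-s window is compared against the window starting one STFT hop
    later.
    """
    from .audio import AudioClip, extract_logmel

    frontend = results.model.frontend
    fold_of = _fold_of_source(results)
    flips, n = 0, 0
    for clip in results.model.clips[:max_clips]:
        net = results.networks[fold_of[clip.source_id]]
        a = AudioClip(clip.samples[: frontend.segment_samples], clip.rate)
        b = AudioClip(clip.samples[hop_samples : hop_samples + frontend.segment_samples], clip.rate)
        pa = forward(net, extract_logmel(a, frontend))
        pb = forward(net, extract_logmel(b, frontend))
        flips += int(np.argmax(pa) != np.argmax(pb))
        n += 1
    return flips / n
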