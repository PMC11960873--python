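"""Fold construction, leakage control, training behavior, evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from caprivox.audio import AudioClip
from caprivox.augment import AugmentationGrid
from caprivox.classes import CLASSES
from caprivox.network import ArchitectureSpec
from caprivox.synthetic import generate_corpus
from caprivox.training import (EvaluationReport, FeatureCache, TrainConfig, evaluate,
                               make_folds, train_fold)


def _manifest(counts: dict[str, int]) -> pd.DataFrame:
    rows = [{"source_id": f"{c}-{i}", "label": c} for c, n in counts.items() for i in range(n)]
    return pd.DataFrame(rows)


class TestMakeFolds:
    def test_exact_divisibility(self):
        plan = make_folds(_manifest({c: 40 for c in CLASSES}), k=5, seed=0)
        for _, test_ids in plan.folds:
            labels = pd.Series([plan.labels[s] for s in test_ids])
            assert labels.value_counts().eq(8).all()

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k"):
            make_folds(_manifest({c: 10 for c in CLASSES}), k=1, seed=0)

    def test_deterministic(self):
        m = _manifest({c: 11 for c in CLASSES})
        assert make_folds(m, 5, 3).folds == make_folds(m, 5, 3).folds

    def test_folds_partition_sources(self):
        m = _manifest({c: 7 for c in CLASSES})
        plan = make_folds(m, 5, 1)
        all_test = [s for _, te in plan.folds for s in te]
        assert sorted(all_test) == sorted(m["source_id"])
        for tr, te in plan.folds:
            assert not set(tr) & set(te)
            assert sorted(tr + te) == sorted(m["source_id"])

    def test_stratification_within_one_sample(self):
        counts = {c: n for c, n in zip(CLASSES, (40, 11, 9, 23, 17, 8, 31, 13))}
        plan = make_folds(_manifest(counts), k=5, seed=2)
        for cls, n in counts.items():
            per_fold = [
                sum(1 for s in te if plan.labels[s] == cls) for _, te in plan.folds
            ]
            assert max(per_fold) - min(per_fold) <= 1, cls

    def test_small_class_named_in_error(self):
        counts = {c: 10 for c in CLASSES}
        counts["reunion"] = 3
        with pytest.raises(ValueError, match="reunion"):
            make_folds(_manifest(counts), k=5, seed=0)


@pytest.fixture(scope="module")
def toy_setup():
    """Separable 2-class corpus, identity-only grid, narrow network."""
    counts = {c: 0 for c in CLASSES}
    counts.update({"heat": 6, "separation": 6})
    corpus = generate_corpus(counts, seed=21)
    grid = AugmentationGrid(stretch_rates=(1.0,), semitone_shifts=(0,))
    cache = FeatureCache(corpus.clips, grid=grid)
    plan = make_folds(corpus.manifest, k=2, seed=21)
    spec = ArchitectureSpec(width_multiplier=0.03125)
    return corpus, cache, plan, spec


class TestTrainFold:
    def test_separable_toy_reaches_full_training_accuracy(self, toy_setup):
        corpus, cache, plan, spec = toy_setup
        cfg = TrainConfig(seed=1, max_epochs=12, learning_rate=1e-3, batch_size=4,
                          k_folds=2, validation_fraction=0.0)
        net, hist = train_fold(cache, plan, 0, spec, cfg)
        assert hist["train_acc"].iloc[-1] == 1.0

    def test_training_loss_non_increasing(self, toy_setup):
        """Without dropout noise, epoch losses decrease on separable data."""
        corpus, cache, plan, _ = toy_setup
        spec = ArchitectureSpec(width_multiplier=0.03125, dropout_rate=0.0)
        cfg = TrainConfig(seed=2, max_epochs=8, learning_rate=5e-4, batch_size=4,
                          k_folds=2, validation_fraction=0.0)
        _, hist = train_fold(cache, plan, 0, spec, cfg)
        losses = hist["train_loss"].to_numpy()
        assert np.all(np.diff(losses) <= 1e-3)

    def test_zero_epochs_returns_initialized_network(self, toy_setup):
        corpus, cache, plan, spec = toy_setup
        cfg = TrainConfig(seed=3, max_epochs=0, k_folds=2)
        net, hist = train_fold(cache, plan, 0, spec, cfg)
        assert hist.empty
        assert net.n_parameters > 0

    def test_seeded_determinism(self, toy_setup):
        corpus, cache, plan, spec = toy_setup
        cfg = TrainConfig(seed=4, max_epochs=2, learning_rate=1e-3, batch_size=4,
                          k_folds=2, validation_fraction=0.0)
        _, h1 = train_fold(cache, plan, 0, spec, cfg)
        _, h2 = train_fold(cache, plan, 0, spec, cfg)
        assert h1["train_loss"].tolist() == h2["train_loss"].tolist()

    def test_bad_fold_index(self, toy_setup):
        corpus, cache, plan, spec = toy_setup
        with pytest.raises(ValueError, match="fold index"):
            train_fold(cache, plan, 5, spec, TrainConfig(k_folds=2))


class TestEvaluate:
    def test_band_energy_oracle_gives_identity_confusion(self, tiny_corpus, frontend):
        """A predictor reading the generator's ground-truth bands is perfect."""
        from caprivox.synthetic import default_specs

        bands = [s.mel_band_indices(frontend) for s in default_specs()]

        def band_oracle(feats: np.ndarray) -> np.ndarray:
            # peak in-band *power* (log features undone): harmonic leakage into
            # foreign bands sits ~50 dB down and noise is 20 dB down, so the
            # true band dominates in the linear domain
            power = np.exp(feats[..., 0])
            scores = np.stack(
                [power[:, lo : hi + 1, :].mean(axis=1).max(axis=1) for lo, hi in bands],
                axis=1,
            )
            out = np.zeros((len(feats), len(CLASSES)))
            out[np.arange(len(feats)), scores.argmax(axis=1)] = 1.0
            return out

        rep = evaluate(band_oracle, tiny_corpus.clips, frontend)
        assert np.allclose(rep.confusion, np.eye(len(CLASSES)))

    def test_uniform_random_predictor_rates_near_chance(self, frontend):
        rng = np.random.default_rng(0)
        n_per_class = 400
        clips = [
            AudioClip(np.zeros(44100, dtype=np.float32), 22050, label=c,
                      source_id=f"{c}-{i}")
            for c in CLASSES for i in range(n_per_class)
        ]

        def random_predictor(feats):
            p = rng.random((len(feats), len(CLASSES)))
            return p / p.sum(axis=1, keepdims=True)

        rep = evaluate(random_predictor, clips, frontend)
        p = 1.0 / len(CLASSES)
        sigma = np.sqrt(p * (1 - p) / n_per_class)
        assert np.all(np.abs(rep.confusion - p) <= 3 * sigma)

    def test_augmented_clip_rejected(self, frontend):
        clip = AudioClip(np.zeros(44100, dtype=np.float32), 22050, label="heat",
                         source_id="x", augmentation=(0.8, 1))
        with pytest.raises(ValueError, match="leakage"):
            evaluate(lambda f: np.ones((len(f), 8)) / 8, [clip], frontend)

    def test_unlabeled_clip_rejected(self, frontend):
        clip = AudioClip(np.zeros(44100, dtype=np.float32), 22050, source_id="x")
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate(lambda f: np.ones((len(f), 8)) / 8, [clip], frontend)

    def test_mean_softmax_aggregation(self, frontend):
        """The clip prediction is the argmax of the mean segment distribution."""
        clip = AudioClip(np.zeros(44100, dtype=np.float32), 22050, label="feed",
                         source_id="agg")
        rows = iter(
            [
                np.array([[0.6, 0.4, 0, 0, 0, 0, 0, 0.0]]),
                np.array([[0.0, 0.9, 0, 0, 0, 0, 0, 0.1]]),
                np.array([[0.4, 0.3, 0, 0, 0, 0, 0, 0.3]]),
            ]
        )

        def seg_predictor(feats):
            return np.concatenate([next(rows) for _ in range(len(feats))])

        rep = evaluate(seg_predictor, [clip], frontend)
        # mean = (0.333, 0.533, ...): argmax is class index 1 ("feed")
        assert rep.confusion[1, 1] == 1.0


class TestReportInvariants:
    def test_rows_sum_to_one(self):
        counts = np.array([[3, 1], [0, 4]])
        conf = counts / counts.sum(axis=1, keepdims=True)
        rep = EvaluationReport(confusion=np.pad(conf, ((0, 6), (0, 6))),
                               counts=np.pad(counts, ((0, 6), (0, 6))))
        assert rep.confusion[:2].sum(axis=1) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_single_class_corpus_rejected(self):
        m = _manifest({"heat": 10})
        with pytest.raises(ValueError):
            make_folds(m, 5, 0)
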