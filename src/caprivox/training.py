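"""Stratified 5-fold cross-validated training and clip-level evaluation.

Folds are stratified by clip label at the source-recording level, so a
clip's segments and all of its augmented variants always share a fold —
augmented near-duplicates can never leak into a test set.  Training uses
the full stretch/shift augmentation grid on training-fold segments;
evaluation always runs on original audio, aggregating segment softmax
outputs by arithmetic mean into one clip-level prediction.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .audio import (AudioClip, FrontendConfig, extract_logmel, logmel_batch,
                    segment, standardize_duration)
from .augment import AugmentationGrid, augment_batch
from .classes import CLASSES, class_index
from .network import ArchitectureSpec, Network, build, forward

__all__ = ["TrainConfig", "FoldPlan", "EvaluationReport", "FeatureCache",
           "make_folds", "train_fold", "evaluate", "cross_validate"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: Adam with learning rate 1e-4, batch size 12, up to 14 epochs
    with early stopping (monitored metric, patience), stratified 5-fold
    cross-validation.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 12
    max_epochs: int = 14
    early_stopping: tuple[str, int] = ("val_loss", 3)
    k_folds: int = 5
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2 (need held-out data)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class FoldPlan:
    """Per-fold train/test source_id lists plus a stratification report."""

    folds: list[tuple[list[str], list[str]]]
    labels: dict[str, str]  # source_id -> class label
    report: pd.DataFrame  # per-fold, per-class test counts

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class EvaluationReport:
    """Row-normalized confusion matrices; diagonal = per-class recall."""

    confusion: np.ndarray  # (|D|, |D|) row-normalized
    counts: np.ndarray  # raw counts
    classes: tuple[str, ...] = CLASSES
    fold_confusions: list[np.ndarray] = field(default_factory=list)

    @property
    def per_class_recall(self) -> np.ndarray:
        return np.diag(self.confusion)

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.per_class_recall))

    def summary(self) -> str:
        lines = ["Clip-level evaluation (rows = true class, diagonal = recall)", ""]
        header = f"{'class':>14s} " + " ".join(f"{c[:6]:>7s}" for c in self.classes)
        lines.append(header)
        for i, c in enumerate(self.classes):
            row = " ".join(f"{v:7.3f}" for v in self.confusion[i])
            lines.append(f"{c:>14s} {row}")
        lines.append("")
        lines.append(f"mean per-class recall: {self.mean_recall:.3f}")
        return "\n".join(lines)


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    out = np.zeros_like(counts, dtype=float)
    np.divide(counts, sums, out=out, where=sums > 0)
    return out


# ---------------------------------------------------------------------------
# folds


def make_folds(manifest: pd.DataFrame, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold split of source recordings; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be at least 2 (k=1 leaves no held-out data)")
    if not {"source_id", "label"} <= set(manifest.columns):
        raise ValueError("manifest must have source_id and label columns")
    sources = manifest.drop_duplicates("source_id")
    labels = dict(zip(sources["source_id"], sources["label"]))
    if sources["label"].nunique() < 2:
        raise ValueError("stratified folds need at least two classes")
    counts = sources["label"].value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"stratification impossible: class(es) {sorted(too_small.index)} have "
            f"fewer than k={k} source recordings"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = sources["source_id"].to_numpy()
    y = sources["label"].to_numpy()
    folds = []
    rows = []
    for fold, (tr, te) in enumerate(skf.split(ids, y)):
        folds.append((list(ids[tr]), list(ids[te])))
        for cls, cnt in pd.Series(y[te]).value_counts().items():
            rows.append({"fold": fold, "class": cls, "test_count": int(cnt)})
    report = pd.DataFrame(rows)
    return FoldPlan(folds=folds, labels=labels, report=report)


# ---------------------------------------------------------------------------
# feature cache


class FeatureCache:
    """Per-source spectrogram store shared across folds.

    Computes (lazily, once) the original-segment log-Mel features of every
    clip and, on demand, the features of the full augmentation grid of those
    segments.  Keeping features in float32 for a 40-clip-per-class corpus
    costs ~350 MB at the default grid.
    """

    def __init__(self, clips: list[AudioClip], config: FrontendConfig = FrontendConfig(),
                 grid: AugmentationGrid = AugmentationGrid()) -> None:
        self.config = config
        self.grid = grid
        self.clips = {c.source_id: c for c in clips}
        if len(self.clips) != len(clips):
            raise ValueError("duplicate source_ids in corpus")
        self._original: dict[str, np.ndarray] = {}
        self._augmented: dict[str, np.ndarray] = {}
        self._segments: dict[str, np.ndarray] = {}

    def _segment_waves(self, source_id: str) -> np.ndarray:
        if source_id not in self._segments:
            clip = standardize_duration(self.clips[source_id], self.config)
            segs = segment(clip, self.config)
            self._segments[source_id] = np.stack([s.samples for s in segs])
        return self._segments[source_id]

    def original(self, source_id: str) -> np.ndarray:
        """(n_segments, n_mels, n_frames) original-segment features."""
        if source_id not in self._original:
            self._original[source_id] = logmel_batch(
                self._segment_waves(source_id), self.config
            ).astype(np.float32)
        return self._original[source_id]

    def augmented(self, source_id: str) -> np.ndarray:
        """(|grid| * n_segments, n_mels, n_frames) augmented-variant features."""
        if source_id not in self._augmented:
            self.precompute_augmented([source_id])
        return self._augmented[source_id]

    def precompute_augmented(self, source_ids: list[str], chunk: int = 48) -> None:
        """Augment many sources in batched phase-vocoder passes.

        Chunking bounds the float64 working set of the vocoder (the cached
        features themselves are float32).
        """
        todo = [s for s in source_ids if s not in self._augmented]
        for i in range(0, len(todo), chunk):
            self._precompute_chunk(todo[i : i + chunk])

    def _precompute_chunk(self, todo: list[str]) -> None:
        if not todo:
            return
        waves = [self._segment_waves(s) for s in todo]
        bounds = np.cumsum([0] + [len(w) for w in waves])
        stacked = np.concatenate(waves)
        variants = augment_batch(stacked, self.grid)
        feats = np.stack(
            [logmel_batch(variants[pair], self.config).astype(np.float32)
             for pair in self.grid.pairs()]
        )  # (|grid|, B, mels, frames)
        for i, sid in enumerate(todo):
            per_source = feats[:, bounds[i] : bounds[i + 1]]
            self._augmented[sid] = per_source.reshape(-1, *per_source.shape[2:]).copy()

    def label(self, source_id: str) -> str:
        return self.clips[source_id].label


# ---------------------------------------------------------------------------
# training


def _gather(cache: FeatureCache, sources: list[str], augmented: bool) -> tuple[np.ndarray, np.ndarray]:
    if augmented:
        cache.precompute_augmented(sources)
    xs, ys = [], []
    for sid in sources:
        feats = cache.augmented(sid) if augmented else cache.original(sid)
        xs.append(feats)
        ys.append(np.full(len(feats), class_index(cache.label(sid)), dtype=np.int64))
    return np.concatenate(xs)[:, :, :, np.newaxis], np.concatenate(ys)


def _eval_loss_acc(net: Network, X: np.ndarray, y: np.ndarray, batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = net.forward_raw(net.normalize(X[i : i + batch]), train=False)
        probs = nn.softmax(logits)
        loss, _ = nn.cross_entropy(probs, y[i : i + batch])
        losses.append(loss * len(logits))
        correct += int((probs.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_fold(
    cache: FeatureCache,
    plan: FoldPlan,
    fold: int,
    spec: ArchitectureSpec = ArchitectureSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Network, pd.DataFrame]:
    """Train one fold's network on the augmented training segments.

    A stratified ``validation_fraction`` of the training sources is held out
    (evaluated on original segments, matching test conditions) for early
    stopping; the best-metric parameters are restored at the end.
    """
    if not 0 <= fold < plan.k:
        raise ValueError(f"fold index {fold} out of range for k={plan.k}")
    train_sources, _ = plan.folds[fold]
    if not train_sources:
        raise ValueError("empty training fold")

    rng = np.random.default_rng([cfg.seed, fold])
    net = build(spec, seed=int(rng.integers(2**31)))
    history = pd.DataFrame(columns=["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
    if cfg.max_epochs == 0:
        return net, history

    y_strat = [plan.labels[s] for s in train_sources]
    if cfg.validation_fraction > 0 and len(train_sources) >= 2 * len(set(y_strat)):
        tr_ids, val_ids = train_test_split(
            train_sources, test_size=cfg.validation_fraction,
            stratify=y_strat, random_state=cfg.seed,
        )
    else:
        tr_ids, val_ids = list(train_sources), []

    X, y = _gather(cache, tr_ids, augmented=True)
    X_val, y_val = (_gather(cache, val_ids, augmented=False) if val_ids else (None, None))

    # input normalization fitted on the training distribution
    net.norm = (float(X.mean()), float(X.std()) + 1e-8)

    opt = nn.Adam(list(dict(net.layers).values()), lr=cfg.learning_rate)
    monitor, patience = cfg.early_stopping
    best_metric, best_weights, since_best = np.inf, None, 0
    records = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(X), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb = net.normalize(X[sel])
            logits = net.forward_raw(xb, train=True)
            probs = nn.softmax(logits)
            loss, grad = nn.cross_entropy(probs, y[sel])
            net.backward(grad)
            opt.step()
            ep_loss += loss * len(sel)
            ep_correct += int((probs.argmax(axis=1) == y[sel]).sum())
        rec = {
            "epoch": epoch,
            "train_loss": ep_loss / len(X),
            "train_acc": ep_correct / len(X),
            "val_loss": np.nan,
            "val_acc": np.nan,
        }
        if X_val is not None:
            rec["val_loss"], rec["val_acc"] = _eval_loss_acc(net, X_val, y_val)
            metric = rec[monitor] if monitor in rec else rec["val_loss"]
            metric = metric if monitor.endswith("loss") else -metric
            if metric < best_metric - 1e-9:
                best_metric, best_weights, since_best = metric, net.get_weights(), 0
            else:
                since_best += 1
                if since_best >= patience:
                    records.append(rec)
                    break
        records.append(rec)
    if best_weights is not None:
        net.set_weights(best_weights)
    history = pd.DataFrame.from_records(records)
    return net, history


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    predictor,
    test_clips: list[AudioClip],
    config: FrontendConfig = FrontendConfig(),
    cache: FeatureCache | None = None,
) -> EvaluationReport:
    """Clip-level confusion matrix on original (never augmented) clips.

    ``predictor`` is a :class:`Network` or any callable mapping an
    (n, n_mels, n_frames, 1) batch to an (n, |D|) probability matrix.  A
    clip's prediction is the argmax of the arithmetic mean of its segments'
    softmax rows.
    """
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64)
    for clip in test_clips:
        if clip.augmentation is not None:
            raise ValueError(
                f"augmented clip {clip.source_id} {clip.augmentation} in test set (leakage)"
            )
        if clip.label is None:
            raise ValueError(f"unlabeled test clip {clip.source_id}")
        if cache is not None:
            feats = cache.original(clip.source_id)[:, :, :, np.newaxis]
        else:
            clip_std = standardize_duration(clip, config)
            feats = np.stack(
                [extract_logmel(s, config).values for s in segment(clip_std, config)]
            )[:, :, :, np.newaxis].astype(np.float32)
        if isinstance(predictor, Network):
            probs = forward(predictor, feats)
        else:
            probs = np.asarray(predictor(feats))
        pred = int(np.argmax(probs.mean(axis=0)))
        counts[class_index(clip.label), pred] += 1
    return EvaluationReport(confusion=_normalize_rows(counts), counts=counts)


def cross_validate(
    clips: list[AudioClip],
    manifest: pd.DataFrame,
    spec: ArchitectureSpec = ArchitectureSpec(),
    cfg: TrainConfig = TrainConfig(),
    grid: AugmentationGrid = AugmentationGrid(),
    config: FrontendConfig = FrontendConfig(),
    return_networks: bool = False,
    verbose: bool = False,
):
    """Run all folds; per-class rates are averaged across fold confusions."""
    plan = make_folds(manifest, cfg.k_folds, cfg.seed)
    cache = FeatureCache(clips, config, grid)
    by_source = {c.source_id: c for c in clips}
    fold_confusions, fold_counts, nets, histories = [], [], [], []
    for fold in range(plan.k):
        t0 = time.time()
        net, history = train_fold(cache, plan, fold, spec, cfg)
        test_clips = [by_source[s] for s in plan.folds[fold][1]]
        rep = evaluate(net, test_clips, config, cache=cache)
        fold_confusions.append(rep.confusion)
        fold_counts.append(rep.counts)
        nets.append(net)
        histories.append(history)
        if verbose:
            print(f"fold {fold}: recall {rep.mean_recall:.3f} ({time.time() - t0:.0f} s)",
                  flush=True)
    mean_conf = np.mean(fold_confusions, axis=0)
    report = EvaluationReport(
        confusion=mean_conf,
        counts=np.sum(fold_counts, axis=0),
        fold_confusions=fold_confusions,
    )
    if return_networks:
        return report, nets, histories, plan, cache
    return report
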