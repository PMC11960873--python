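"""Model/results interface tying the pipeline together.

:class:`GoatCallClassifier` is constructed from a labeled clip collection
(real recordings via a manifest, or the bundled synthetic generator) plus
the architecture / training / augmentation configuration.  ``fit()`` runs
stratified k-fold cross-validated training and returns a
:class:`ClassifierResults` carrying the per-fold networks, confusion
matrices and training histories; prediction, explanation, retrieval and
class-heatmap aggregation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioClip, FrontendConfig, extract_logmel, load_clip, read_manifest, segment, standardize_duration
from .augment import AugmentationGrid
from .classes import CLASSES, class_index
from .explain import ClassHeatmap, ClassHeatmapSpec, class_average_heatmap
from .interact import answer_influence, find_dissimilar, find_similar, relevance_difference
from .network import ArchitectureSpec, Network, forward
from .synthetic import generate_corpus
from .training import EvaluationReport, FeatureCache, FoldPlan, TrainConfig, cross_validate

__all__ = ["GoatCallClassifier", "ClassifierResults"]


class GoatCallClassifier:
    """Cross-validated convolutional classifier of labeled vocalization clips."""

    def __init__(
        self,
        clips: list[AudioClip],
        manifest: pd.DataFrame | None = None,
        arch: ArchitectureSpec = ArchitectureSpec(),
        train_config: TrainConfig = TrainConfig(),
        grid: AugmentationGrid = AugmentationGrid(),
        frontend: FrontendConfig = FrontendConfig(),
    ) -> None:
        if manifest is None:
            manifest = pd.DataFrame(
                [{"source_id": c.source_id, "label": c.label} for c in clips]
            )
        self.clips = clips
        self.manifest = manifest
        self.arch = arch
        self.train_config = train_config
        self.grid = grid
        self.frontend = frontend

    @classmethod
    def from_synthetic(
        cls,
        n_per_class: int | dict[str, int] = 40,
        seed: int = 7,
        **kwargs,
    ) -> "GoatCallClassifier":
        """Build from the synthetic 8-class call generator."""
        corpus = generate_corpus(n_per_class, seed=seed)
        return cls(corpus.clips, corpus.manifest, **kwargs)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, **kwargs) -> "GoatCallClassifier":
        """Build from a CSV manifest with columns path, label, source_id."""
        frontend = kwargs.get("frontend", FrontendConfig())
        manifest = read_manifest(manifest_path)
        clips = [
            load_clip(row["path"], label=row["label"], source_id=row["source_id"], config=frontend)
            for _, row in manifest.iterrows()
        ]
        return cls(clips, manifest[["source_id", "label"]], **kwargs)

    def fit(self, verbose: bool = False) -> "ClassifierResults":
        """Run stratified k-fold cross-validated training and evaluation."""
        report, nets, histories, plan, cache = cross_validate(
            self.clips,
            self.manifest,
            self.arch,
            self.train_config,
            self.grid,
            self.frontend,
            return_networks=True,
            verbose=verbose,
        )
        return ClassifierResults(
            model=self,
            report=report,
            networks=nets,
            histories=histories,
            plan=plan,
            cache=cache,
        )


@dataclass
class ClassifierResults:
    """Cross-validation outcome: estimates, diagnostics and tools."""

    model: GoatCallClassifier
    report: EvaluationReport
    networks: list[Network]
    histories: list[pd.DataFrame]
    plan: FoldPlan
    cache: FeatureCache
    _best_fold: int = field(init=False)

    def __post_init__(self) -> None:
        recalls = [float(np.mean(np.diag(c))) for c in self.report.fold_confusions]
        self._best_fold = int(np.argmax(recalls))

    # -- headline quantities ------------------------------------------------

    @property
    def mean_recall(self) -> float:
        return self.report.mean_recall

    @property
    def per_class_recall(self) -> pd.Series:
        return pd.Series(self.report.per_class_recall, index=list(self.report.classes))

    @property
    def confusion(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.report.confusion, index=list(self.report.classes), columns=list(self.report.classes)
        )

    @property
    def network(self) -> Network:
        """The representative (best-recall) fold network."""
        return self.networks[self._best_fold]

    def summary(self) -> str:
        cfg = self.model.train_config
        arch = self.model.arch
        lines = [
            "Goat-vocalization classifier — stratified cross-validation",
            "=" * 60,
            f"clips: {len(self.model.clips)}   classes: {len(self.report.classes)}"
            f"   folds: {cfg.k_folds}",
            f"architecture: blocks {arch.block_filters} x{arch.convs_per_block} convs,"
            f" dense {arch.effective_dense}, width {arch.width_multiplier}",
            f"optimizer: {cfg.optimizer} lr={cfg.learning_rate} batch={cfg.batch_size}"
            f" epochs<= {cfg.max_epochs}",
            f"augmentation grid: {self.model.grid.cardinality} variants/segment",
            "",
            self.report.summary(),
        ]
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, clip: AudioClip) -> np.ndarray:
        """Mean-softmax class distribution for one clip."""
        std = standardize_duration(clip, self.model.frontend)
        feats = [extract_logmel(s, self.model.frontend) for s in segment(std, self.model.frontend)]
        return forward(self.network, feats).mean(axis=0)

    def predict(self, clip: AudioClip) -> str:
        return CLASSES[int(np.argmax(self.predict_proba(clip)))]

    # -- explanation and interaction ----------------------------------------

    def explain(self, clip: AudioClip, percentile: float = 90.0) -> dict:
        """Relevance map, high-relevance region and sonification for a clip."""
        return answer_influence(self.network, clip, self.model.frontend, percentile)

    def find_similar(self, clip: AudioClip, top_k: int = 5):
        return find_similar(self.network, clip, self.model.clips, top_k, self.model.frontend)

    def find_dissimilar(self, clip: AudioClip, top_k: int = 5):
        return find_dissimilar(self.network, clip, self.model.clips, top_k, self.model.frontend)

    def compare(self, clip_a: AudioClip, clip_b: AudioClip, percentile: float = 90.0) -> dict:
        return relevance_difference(self.network, clip_a, clip_b, self.model.frontend, percentile)

    def class_heatmaps(
        self,
        n_spectrograms: int = 8,
        g_channels: int = 2,
        layers: list[str] | None = None,
    ) -> dict[str, ClassHeatmap]:
        """Class-wise average relevance heatmaps over central class samples.

        Defaults are desk-scale; pass larger ``n_spectrograms`` / ``g_channels``
        for corpus-scale aggregation.
        """
        if layers is None:
            layers = ["block_4/conv_2", "fc_1"]
        net = self.network
        spec = ClassHeatmapSpec(
            dictionary_size=len(CLASSES),
            n_spectrograms=n_spectrograms,
            g_channels=g_channels,
        )
        out: dict[str, ClassHeatmap] = {}
        for cls_name in CLASSES:
            sids = [c.source_id for c in self.model.clips if c.label == cls_name]
            if not sids:
                continue
            feats = np.concatenate([self.cache.original(s) for s in sids])
            n_use = min(n_spectrograms, len(feats))
            out[cls_name] = class_average_heatmap(
                net, feats, cls_name, class_index(cls_name), layers,
                ClassHeatmapSpec(len(CLASSES), n_use, g_channels),
            )
        return out

    # -- plotting -----------------------------------------------------------

    def plot_confusion(self, path: str | Path | None = None):
        """Heatmap of the fold-averaged confusion matrix."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.report.confusion, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(CLASSES)), CLASSES, rotation=45, ha="right")
        ax.set_yticks(range(len(CLASSES)), CLASSES)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax, label="rate")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_heatmap(self, heatmap: np.ndarray, path: str | Path | None = None, title: str = ""):
        """Render a relevance heatmap over the log-Mel plane."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        lim = float(np.abs(heatmap).max()) or 1.0
        im = ax.imshow(heatmap, origin="lower", aspect="auto", cmap="bwr", vmin=-lim, vmax=lim)
        ax.set_xlabel("frame")
        ax.set_ylabel("mel band")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="relevance")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
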