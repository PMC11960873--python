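"""Run configuration: one YAML document describing a full pipeline run.

The configuration round-trips losslessly through YAML; unknown keys are
rejected so typos fail loudly.  A single global seed fans out to per-stage
seeds through independent seed sequences, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .audio import FrontendConfig
from .augment import AugmentationGrid
from .network import ArchitectureSpec
from .training import TrainConfig

__all__ = ["ExplainConfig", "RunConfig", "stage_seed"]

_STAGES = ("corpus", "folds", "training", "explain")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([global_seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ExplainConfig:
    """Heatmap-aggregation parameters: n central samples, g channels, top-k."""

    n_spectrograms: int = 8
    g_channels: int = 2
    top_k: int = 6
    layers: tuple[str, ...] = ("block_4/conv_2", "fc_1")
    percentile: float = 90.0


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in data[f.name]
            )
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 7
    n_per_class: int = 40
    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    grid: AugmentationGrid = field(default_factory=AugmentationGrid)
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        sub = {
            "frontend": FrontendConfig,
            "grid": AugmentationGrid,
            "arch": ArchitectureSpec,
            "train": TrainConfig,
            "explain": ExplainConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = _build(sub[key], dict(value))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
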