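from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caprivox.audio import AudioClip, FrontendConfig
from caprivox.synthetic import generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frontend() -> FrontendConfig:
    return FrontendConfig()


@pytest.fixture(scope="session")
def tone_segment() -> AudioClip:
    """One second of a 1 kHz tone at 22 050 Hz."""
    t = np.arange(22050) / 22050
    return AudioClip((0.5 * np.sin(2 * np.pi * 1000 * t)).astype(np.float32), 22050)


@pytest.fixture(scope="session")
def noise_segment() -> AudioClip:
    rng = np.random.default_rng(123)
    return AudioClip((0.1 * rng.standard_normal(22050)).astype(np.float32), 22050)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Two clips per class; enough to exercise segmentation/feature paths."""
    return generate_corpus(2, seed=11)


@pytest.fixture(scope="session")
def crossval_results():
    """The desk-scale cross-validation experiment (shared across tests).

    Computed once per session: synthetic corpus of 40 clips per class,
    width-0.125 network, stratified 5-fold cross-validation with full
    augmentation of training folds.
    """
    from caprivox.experiments import desk_scale_crossval

    return desk_scale_crossval(seed=7)
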