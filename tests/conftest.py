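"""Shared fixtures: small synthetic corpora generated at test time."""

from dataclasses import replace

import numpy as np
import pytest

from pollenstage import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """A compact slide: big enough for a few patches, quick to render."""
    return synth.SynthConfig(
        slide_width=1024, slide_height=512, patch_size=256,
        grain_density=12.0, impurity_density=4.0, bubble_density=4.0,
        class_weights=tuple([1 / 8] * 8), seed=7,
    )


@pytest.fixture(scope="session")
def small_slide(small_config):
    return synth.generate_slide(small_config)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return synth.generate_corpus(small_config, 2)


@pytest.fixture(scope="session")
def dense_corpus():
    """Higher grain load for classifier training."""
    cfg = synth.SynthConfig(
        slide_width=2048, slide_height=1024, patch_size=256,
        grain_density=20.0, impurity_density=1.0, bubble_density=1.0,
        class_weights=tuple([1 / 8] * 8), seed=11,
    )
    return synth.generate_corpus(cfg, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
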