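import numpy as np
import pytest

from fieldlift import spectral_core as sc
from fieldlift.dataset_generator import AugmentationConfig, CorpusConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_666)


@pytest.fixture
def small_axis_hf():
    """4,600-point window at 400 MHz (same ppm bounds as the full axis)."""
    return sc.make_axis(4_600, -0.32, 10.2, 400.0)


@pytest.fixture
def small_axis_lf(small_axis_hf):
    return small_axis_hf.with_freq(100.0)


@pytest.fixture
def tiny_library():
    return sc.builtin_library(5)


@pytest.fixture
def default_aug():
    return AugmentationConfig()


@pytest.fixture
def toy_corpus_cfg():
    """20 paired samples split 16:4 on a small axis."""
    return CorpusConfig(
        n_all_present=10, n_with_dropout=10, train_count=16, val_count=4,
        test_count=2, seed=7, n_points=460,
    )
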