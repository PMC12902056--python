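import numpy as np
import pytest

from sacbias.image_features import SaliencyMap
from sacbias.synthetic_data import CorpusSpec, default_truth_params
from sacbias.target_model import CombinationWeights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def truth_params():
    return default_truth_params()


@pytest.fixture(scope="session")
def uniform_map():
    """Uniform allocentric map on the standard synthetic grid (64 px, 0.35 deg/px)."""
    return SaliencyMap(np.full((64, 64), 1.0 / 4096), 0.35)


@pytest.fixture(scope="session")
def small_corpus_spec():
    return CorpusSpec(n_images=5, size_px=64, deg_per_px=0.35, rng_seed=7)


@pytest.fixture(scope="session")
def default_weights():
    return CombinationWeights()
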