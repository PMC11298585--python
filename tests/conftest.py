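import numpy as np
import pytest

from lactamscan import reference as ref
from lactamscan import synthetic_data as synth
from lactamscan.te_classifier import ScreenConfig, default_anchors


@pytest.fixture(scope="session")
def anchors():
    return default_anchors()


@pytest.fixture(scope="session")
def config():
    return ScreenConfig()


@pytest.fixture(scope="session")
def sulm():
    return ref.sulm_record()


@pytest.fixture(scope="session")
def sulte():
    return ref.sulte_record()


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def candidate_cluster():
    """Sulfazecin-like cluster with all four features planted, no mutation."""
    cluster, truth = synth.make_cluster(synth.GeneratorSpec(seed=7))
    return cluster, truth
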