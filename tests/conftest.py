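import numpy as np
import pytest

from polfid.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cfg():
    """Fast simulation settings for unit tests."""
    return SimConfig(seed=0, n_cultures=20, m_true=2.0, epsilon=1.0, Nt=10**9)


# printed six-class counts (order CG->GC, CG->AT, CG->TA, AT->TA, AT->CG, AT->GC)
# for the four strains of the mutation-spectrum table
SPECTRUM_CLASS_COUNTS = {
    "dnaE_wt": (2, 8, 9, 89, 174, 20),
    "dnaE_S759C": (5, 15, 12, 316, 10, 13),
    "dnaE_S759N": (0, 0, 104, 140, 3, 80),
    "dnaE_S759T": (0, 5, 106, 152, 1, 80),
}


@pytest.fixture
def spectrum_class_counts():
    return SPECTRUM_CLASS_COUNTS
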