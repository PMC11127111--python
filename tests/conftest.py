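import numpy as np
import pytest

from biomevol.mk import RateMatrix
from biomevol.simulate import BDParams, simulate_bd_tree
from biomevol.trees import read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def two_tip_tree():
    return read_newick("(A:1,B:1):0;")


@pytest.fixture(scope="session")
def yule500():
    """One 500-tip pure-birth tree shared by the larger statistical tests."""
    return simulate_bd_tree(BDParams(1.0, 0.0, n=500), seed=1905)


@pytest.fixture
def er2_q():
    return RateMatrix.from_rates(np.full((2, 2), 0.3), ["0", "1"])


def random_rate_matrix(rng, S, scale=1.0):
    off = rng.uniform(0.1, 1.0, (S, S)) * scale
    return RateMatrix.from_rates(off, [f"s{i}" for i in range(S)])
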