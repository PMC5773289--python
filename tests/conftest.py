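import numpy as np
import pytest

import labile as lb


@pytest.fixture
def cherry():
    return lb.read_newick("(A:1,B:1);")


@pytest.fixture
def three_taxon():
    return lb.read_newick("((A:1.0,B:2.0):0.5,C:1.5);")


@pytest.fixture
def four_taxon_ultrametric():
    return lb.read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def yule20():
    return lb.simulate_yule_tree(20, seed=11, depth=50.0)


@pytest.fixture
def er2(scope="session"):
    """2-state symmetric rate matrix, q = 0.3/My."""
    return lb.RateMatrix(np.array([[-0.3, 0.3], [0.3, -0.3]]),
                         ("present", "absent"), "SYM")
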