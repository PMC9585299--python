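import numpy as np
import pandas as pd
import pytest

from divgrad import CommunityMatrix, TraitTable, parse_newick


@pytest.fixture
def small_cm():
    counts = np.array([[3, 0, 1], [0, 2, 2]])
    return CommunityMatrix(("p1", "p2"), ("A", "B", "C"), counts)


@pytest.fixture
def worked_tree():
    """Hand-checkable 3-tip tree: depths A = B = C = 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def linear_traits():
    """Three taxa whose traits sit at 0, 1/2 and 1 of every trait range."""
    return TraitTable(pd.DataFrame(
        {"SLA": [10.0, 20.0, 30.0], "LT": [0.1, 0.2, 0.3],
         "WD": [0.4, 0.5, 0.6]},
        index=["t1", "t2", "t3"],
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_abundances(rng, n=None, max_n=25):
    n = n or int(rng.integers(2, max_n))
    p = rng.dirichlet(np.full(n, 0.5))
    p = p[p > 1e-12]
    return p / p.sum()
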