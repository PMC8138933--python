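import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from micromed import synthdata as sd


@pytest.fixture(scope="session")
def star_tree():
    """Five unit-length leaves hanging directly off the root."""
    return TreeNode.read(io.StringIO("(a:1,b:1,c:1,d:1,e:1)root;"))


@pytest.fixture(scope="session")
def taxonomy():
    """Study-sized taxonomy: 45 genera in 25 families."""
    return sd.make_taxonomy(45, 25, seed=1)


@pytest.fixture(scope="session")
def design():
    return sd.StudyDesign(n_per_cell=8, seed=0)


@pytest.fixture(scope="session")
def study_data(design, taxonomy):
    counts, meta, truth = sd.sample_counts(design, taxonomy, seed=11)
    return counts, meta, truth


def logistic_normal_z(rng, n, p):
    """iid logistic-normal log relative abundances (rows of exp sum to 1)."""
    logits = rng.normal(0.0, 1.0, (n, p))
    x = np.exp(logits)
    x /= x.sum(axis=1, keepdims=True)
    return np.log(x)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
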