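import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from habspec.core_io import CommunityTable


@pytest.fixture
def example_tree():
    """((A:1,B:1):1,C:2); — the worked three-tip example."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def star_tree():
    return TreeNode.read(io.StringIO("(t1:1,t2:1,t3:1,t4:1);"))


@pytest.fixture
def tiny_table():
    return CommunityTable(pd.DataFrame(
        [[1, 2], [0, 5], [3, 0]],
        index=["s1", "s2", "s3"], columns=["A", "B"]))


def random_table(rng, n_samples=10, n_otus=20, depth=200, prefix="s"):
    p = rng.dirichlet(np.ones(n_otus))
    counts = np.array([rng.multinomial(depth, p) for _ in range(n_samples)])
    counts[:, 0] += 1  # no all-zero sample
    return CommunityTable(pd.DataFrame(
        counts, index=[f"{prefix}{i}" for i in range(n_samples)],
        columns=[f"OTU{j:03d}" for j in range(n_otus)]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
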