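"""Shared fixtures: small hand-checkable trees and tables, synthetic worlds."""

import numpy as np
import pytest

from postkm.kernels import OTUTable
from postkm.simulate import synthetic_params, synthetic_tree
from postkm.tree import cophenetic_distances, read_newick


@pytest.fixture(scope="session")
def three_leaf_tree():
    """((A:1,B:1):1,C:2); — d_AB=2, d_AC=4, d_BC=4 by hand path sums."""
    return read_newick("((A:1,B:1):1,C:2);", is_path=False)


@pytest.fixture(scope="session")
def three_leaf_dist(three_leaf_tree):
    return cophenetic_distances(three_leaf_tree, ["A", "B", "C"])


@pytest.fixture
def small_table():
    """4 samples x 3 taxa count table with easy CLR arithmetic."""
    Z = np.array(
        [
            [1.0, 1.0, 1.0],
            [0.0, 3.0, 1.0],
            [5.0, 0.0, 2.0],
            [2.0, 2.0, 8.0],
        ]
    )
    return OTUTable(
        samples=["S1", "S2", "S3", "S4"], taxa=["A", "B", "C"], Z=Z, mode="counts"
    )


@pytest.fixture(scope="session")
def small_world():
    """M=60 synthetic world: clustered tree + DM parameters + distances."""
    M = 60
    tree = synthetic_tree(M=M, seed=11)
    labels = [f"OTU{m+1}" for m in range(M)]
    dist = cophenetic_distances(tree, labels)
    params = synthetic_params(M=M, seed=11)
    return {"M": M, "tree": tree, "labels": labels, "dist": dist, "params": params}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
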