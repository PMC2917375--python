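"""Shared fixtures: small hypergraph systems and trees built in memory."""

import numpy as np
import pytest

from hyperevo.fixtures import make_toy_system
from hyperevo.hypernet import EdgeMask, Reaction, build_reference
from hyperevo.phylo import read_newick


@pytest.fixture(scope="session")
def toy():
    return make_toy_system()


@pytest.fixture(scope="session")
def chain4():
    """Four reactions in a metabolic chain A->B->C->D->E (path neighbor graph)."""
    return build_reference(
        [
            Reaction("r1", {"A"}, {"B"}),
            Reaction("r2", {"B"}, {"C"}),
            Reaction("r3", {"C"}, {"D"}),
            Reaction("r4", {"D"}, {"E"}),
        ]
    )


@pytest.fixture(scope="session")
def chain8():
    """Eight-reaction path system used for the partition golden trace."""
    mets = "ABCDEFGHI"
    return build_reference(
        [
            Reaction(f"e{i}", {mets[i]}, {mets[i + 1]})
            for i in range(8)
        ]
    )


@pytest.fixture()
def three_leaf_tree():
    return read_newick("((X:0.4,Y:0.7):0.3,Z:0.6);")


@pytest.fixture()
def no_mask():
    return EdgeMask()


def random_states(M, n, seed):
    rng = np.random.default_rng(seed)
    return [rng.integers(0, 2, M).astype(np.int8) for _ in range(n)]
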