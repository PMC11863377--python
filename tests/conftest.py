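import numpy as np
import pytest

import cliquemap as cm


@pytest.fixture(scope="session")
def enol():
    """Enol -> aldehyde tautomerisation: the standard desk-check reaction."""
    return cm.parse_reaction("CC=CO>>CCC=O")


@pytest.fixture(scope="session")
def symmetric_rxn():
    """Branched -> linear C3O skeleton with two equivalent reactant methyls."""
    return cm.parse_reaction("CC(C)O>>CCCO")


def random_adjacency(n: int, p: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    return adj


def complement_of_matching(k: int) -> np.ndarray:
    """Complete graph on 2k vertices minus a perfect matching.

    Its maximum cliques are exactly the 2^k ways to pick one endpoint per
    matching edge, each of size k.
    """
    n = 2 * k
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    for i in range(k):
        adj[2 * i, 2 * i + 1] = adj[2 * i + 1, 2 * i] = False
    return adj
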