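import numpy as np
import pytest

from patternet.io import InteractionEdge
from patternet.network import GeneNetwork, build_network
from patternet.patterns import PatternGroup
from patternet.synth import BACKGROUND_MODULE, SyntheticTruth


def make_edges(pairs, score=700):
    """Scored undirected edges from (a, b) pairs."""
    return [InteractionEdge(a, b, score) for a, b in pairs]


def make_network(pairs, groups, curated=(), score=700) -> GeneNetwork:
    """Small labelled network from explicit pairs and a gene->group map."""
    return build_network(make_edges(pairs, score), groups.keys(), groups, curated)


def make_truth(module_sizes, prefix="n") -> SyntheticTruth:
    """Ground truth with explicit modules and no expression component.

    module_sizes maps a PatternGroup (or BACKGROUND_MODULE) to a node count.
    """
    groups, effects, modules = {}, {}, {}
    i = 0
    for mod, size in module_sizes.items():
        for _ in range(size):
            gene = f"{prefix}{i:04d}"
            if mod == BACKGROUND_MODULE:
                groups[gene] = PatternGroup.NONE
                modules[gene] = BACKGROUND_MODULE
            else:
                groups[gene] = mod
                modules[gene] = mod.value
            effects[gene] = (1.0, 1.0)
            i += 1
    return SyntheticTruth(groups=groups, effects=effects, modules=modules, params={}, seed=None)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_graph_network(n, p, seed, group=PatternGroup.G2):
    """Erdos-Renyi network with all nodes in one group; None if it has no edge."""
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n)]
    pairs = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not pairs:
        return None
    return make_network(pairs, {v: group for v in nodes})
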