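from __future__ import annotations

import numpy as np
import pytest

from cgabni.core import BooleanNetwork, NCFRule

from oracles import random_rule


def make_network(rule_specs, n_genes=None):
    """Build a network from {target: (tuples, ...)} with auto gene names."""
    n = n_genes or len(rule_specs)
    names = tuple(f"v{i + 1}" for i in range(n))
    rules = tuple(NCFRule(i, tuple(rule_specs[i])) for i in range(n))
    return BooleanNetwork(names, rules)


def random_network(rng, n_genes, max_k=3):
    """Random NCF network where every gene has 1..max_k regulators."""
    rules = []
    for i in range(n_genes):
        k = int(rng.integers(1, min(max_k, n_genes - 1) + 1))
        rules.append(NCFRule(i, random_rule(rng, n_genes, i, k)))
    names = tuple(f"v{i + 1}" for i in range(n_genes))
    return BooleanNetwork(names, tuple(rules))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_mutual_activation():
    """Two genes activating each other: 10 <-> 01 is a period-2 cycle."""
    return make_network({0: [(1, 1, 1)], 1: [(0, 1, 1)]})
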