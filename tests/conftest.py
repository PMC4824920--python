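import numpy as np
import pytest

import cophylo as cp


@pytest.fixture
def congruent_pair():
    """Identical 4-leaf topologies with identity links (perfect congruence)."""
    host = cp.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    symb = cp.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
    links = cp.AssociationMap([("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")])
    return host, symb, links


@pytest.fixture
def incongruent_triple():
    """Host ((A,B),C) against symbiont ((a,c),b): one switch is optimal."""
    host = cp.read_newick("((A:1,B:1):1,C:1);")
    symb = cp.read_newick("((a:1,c:1):1,b:1);")
    links = cp.AssociationMap([("A", "a"), ("B", "b"), ("C", "c")])
    return host, symb, links


@pytest.fixture
def fixture_table():
    return cp.make_infection_fixture()


def random_links(rng, host, symb):
    hosts = host.leaf_labels
    return cp.AssociationMap(
        [(hosts[int(rng.integers(len(hosts)))], s) for s in symb.leaf_labels]
    )


def uniform_cell_links(rng, host, symb, n_links=None):
    """Links drawn uniformly over distinct host x symbiont cells.

    This is the same distribution the full-shuffle permutation null redraws
    from, so permutation tests on these links are exactly exchangeable.
    """
    hosts, symbs = host.leaf_labels, symb.leaf_labels
    n = n_links or len(symbs)
    cells = rng.choice(len(hosts) * len(symbs), size=n, replace=False)
    return cp.AssociationMap(
        [(hosts[int(c) // len(symbs)], symbs[int(c) % len(symbs)]) for c in cells]
    )
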