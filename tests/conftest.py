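"""Shared fixtures: hand-built reference networks and a small trained model."""

from __future__ import annotations

import random

import pytest

from cphnet.cps import CherrySeq
from cphnet.ml import make_training_set, train_classifier
from cphnet.phylo import PhyloNetwork, PhyloTree
from cphnet.reconstruct import network_from_cps
from cphnet.simgen import exhaustive_trees, generate_lgt


@pytest.fixture
def cherry_network() -> PhyloNetwork:
    """((x,y),z) with known branch lengths: (x, y) is a cherry."""
    n = PhyloTree()
    root = n.new_node()
    n.root = root
    a = n.new_node()
    p = n.new_node()
    x, y, z = n.new_node(), n.new_node(), n.new_node()
    n.add_edge(root, a, 1.0)
    n.add_edge(a, p, 2.0)   # edge (p(p(x)), p(x))
    n.add_edge(p, x, 2.0)
    n.add_edge(p, y, 4.0)   # edge (p(x), y)
    n.add_edge(a, z, 5.0)
    for node, lab in ((x, "x"), (y, "y"), (z, "z")):
        n.set_label(node, lab)
    n.validate()
    return n


@pytest.fixture
def reticulated_cherry_network() -> PhyloNetwork:
    """A network in which (x, y) is a reticulated cherry.

    p(x) is a reticulation fed by p(y) (a tree node) and by another edge.
    """
    n = PhyloNetwork()
    root = n.new_node()
    n.root = root
    top = n.new_node()
    py = n.new_node()    # p(y), a tree node and a parent of the reticulation
    w2 = n.new_node()    # the reticulation's other (tree-node) parent
    ret = n.new_node()   # p(x)
    x, y, z = n.new_node(), n.new_node(), n.new_node()
    n.add_edge(root, top, 1.0)
    n.add_edge(top, py, 1.0)
    n.add_edge(top, w2, 1.0)
    n.add_edge(py, ret, 1.0)   # (p(y), p(x))
    n.add_edge(py, y, 3.0)     # (p(y), y)
    n.add_edge(w2, ret, 1.0)
    n.add_edge(w2, z, 1.0)
    n.add_edge(ret, x, 2.0)    # (p(x), x)
    for node, lab in ((x, "x"), (y, "y"), (z, "z")):
        n.set_label(node, lab)
    n.validate()
    return n


@pytest.fixture
def example_network():
    """The r=1 network reconstructed from S = (y,x),(y,z),(w,x),(x,z)."""
    return network_from_cps(CherrySeq([("y", "x"), ("y", "z"), ("w", "x"), ("x", "z")]))


@pytest.fixture
def example_trees(example_network):
    """The two exhaustive trees displayed by the r=1 example network."""
    trees = exhaustive_trees(example_network)
    assert len(trees) == 2
    return trees


@pytest.fixture(scope="session")
def small_classifier():
    """A cherry classifier trained on a small batch of LGT networks."""
    rng = random.Random(1234)
    nets = []
    for _ in range(25):
        leaves = rng.randint(5, 15)
        rets = rng.randint(1, min(4, leaves - 2))
        nets.append(generate_lgt(leaves, rets, seed=rng.randrange(2**31)))
    data = make_training_set(nets, seed=7)
    clf, report = train_classifier(data, seed=7)
    clf.metadata["holdout_accuracy"] = report["holdout_accuracy"]
    return clf


def random_instance(seed: int, max_taxa: int = 5, max_trees: int = 4):
    """A small random instance: subset trees of an LGT network, some leaves
    possibly dropped.  Returns (generating network, tree list)."""
    from cphnet.simgen import remove_leaves, sample_displayed_trees

    rng = random.Random(seed)
    leaves = rng.randint(4, max_taxa)
    rets = rng.randint(0, 2)
    net = generate_lgt(leaves, rets, seed=rng.randrange(2**31))
    n_trees = rng.randint(1, max_trees)
    trees = sample_displayed_trees(net, n_trees, seed=rng.randrange(2**31))
    if rng.random() < 0.3 and leaves >= 5:
        trees = remove_leaves(trees, 20.0, seed=rng.randrange(2**31)) or trees
    return net, trees
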