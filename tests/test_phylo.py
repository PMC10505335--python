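"""Cherry/reticulated-cherry mechanics, pair round trips and the display oracle."""

from __future__ import annotations

import itertools
import random

import pytest

from cphnet.cps import CherrySeq
from cphnet.phylo import (
    InvalidSequenceError,
    PairKind,
    PhyloNetwork,
    PhyloTree,
    add_pair,
    classify_pair,
    displays,
    height_pair,
    isomorphic,
    reduce_pair,
    reducible_pairs,
    restrict_tree,
    tree_canonical,
)
from cphnet.io import tree_from_newick
from cphnet.reconstruct import network_from_cps
from cphnet.simgen import generate_lgt


class TestClassify:
    def test_cherry(self, cherry_network):
        assert classify_pair(cherry_network, ("x", "y")) is PairKind.CHERRY
        assert classify_pair(cherry_network, ("y", "x")) is PairKind.CHERRY
        assert classify_pair(cherry_network, ("x", "z")) is PairKind.NONE

    def test_reticulated_cherry_is_ordered(self, reticulated_cherry_network):
        n = reticulated_cherry_network
        assert classify_pair(n, ("x", "y")) is PairKind.RETICULATED_CHERRY
        assert classify_pair(n, ("y", "x")) is PairKind.NONE
        assert classify_pair(n, ("x", "z")) is PairKind.RETICULATED_CHERRY

    def test_absent_leaf_gives_none(self, cherry_network):
        assert classify_pair(cherry_network, ("x", "missing")) is PairKind.NONE
        assert classify_pair(cherry_network, ("x", "x")) is PairKind.NONE

    def test_trees_never_have_reticulated_cherries(self):
        t = tree_from_newick("(((a,b),c),(d,e));")
        for x, y in itertools.permutations("abcde", 2):
            assert classify_pair(t, (x, y)) in (PairKind.CHERRY, PairKind.NONE)


class TestReduce:
    def test_cherry_reduction_sums_lengths(self, cherry_network):
        out, affected = reduce_pair(cherry_network, ("x", "y"))
        assert affected
        out.validate()
        assert out.leaves == {"y", "z"}
        # (p(p(x)), p(x)) of length 2 and (p(x), y) of length 4 merge to 6
        yn = out.leaf_node("y")
        assert out.length(out.parent(yn), yn) == pytest.approx(6.0)

    def test_reticulated_cherry_reduction(self, reticulated_cherry_network):
        out, affected = reduce_pair(reticulated_cherry_network, ("x", "y"))
        assert affected
        out.validate()
        assert out.reticulation_number() == 0
        # surviving x edge merges (z-side parent, p(x)) with (p(x), x): 1 + 2
        xn = out.leaf_node("x")
        assert out.length(out.parent(xn), xn) == pytest.approx(3.0)

    def test_non_reducible_pair_is_noop(self, cherry_network):
        out, affected = reduce_pair(cherry_network, ("x", "z"))
        assert not affected
        assert isomorphic(out, cherry_network)

    def test_two_leaf_tree_fully_reduces(self):
        t = PhyloTree.from_cherry("x", "y")
        assert t.reduce_pair(("x", "y"))
        assert t.is_fully_reduced()
        assert t.leaves == {"y"}


class TestAddPair:
    def test_empty_network_becomes_cherry(self):
        n = PhyloNetwork()
        n.add_pair(("w", "y"))
        n.validate()
        assert n.classify_pair(("w", "y")) is PairKind.CHERRY

    def test_existing_first_element_gets_reticulation(self):
        n = PhyloNetwork()
        n.add_pair(("x", "y"))
        n.add_pair(("x", "y"))
        n.validate()
        assert n.reticulation_number() == 1
        assert n.classify_pair(("x", "y")) is PairKind.RETICULATED_CHERRY

    def test_absent_second_element_is_error(self):
        n = PhyloNetwork()
        n.add_pair(("x", "y"))
        with pytest.raises(InvalidSequenceError):
            n.add_pair(("a", "b"))

    @pytest.mark.parametrize("seed", range(12))
    def test_reduce_add_round_trip(self, seed):
        """Reducing any reducible pair and adding it back restores the network."""
        rng = random.Random(seed)
        net = generate_lgt(
            rng.randint(4, 8), rng.randint(0, 5), seed=rng.randrange(2**31)
        )
        for pair in reducible_pairs(net):
            red, affected = reduce_pair(net, pair)
            assert affected
            red.validate()
            assert red.num_edges() < net.num_edges()
            back = add_pair(red, pair)
            back.validate()
            assert isomorphic(back, net), (pair, seed)


class TestHeights:
    def test_cherry_heights(self, cherry_network):
        hx, hy, h = height_pair(cherry_network, ("x", "y"))
        assert (hx, hy, h) == (2.0, 4.0, 3.0)

    def test_reticulated_cherry_heights(self, reticulated_cherry_network):
        hx, hy, h = height_pair(reticulated_cherry_network, ("x", "y"))
        # h_x = l(p(y),p(x)) + l(p(x),x) = 1 + 2; h_y = l(p(y),y) = 3
        assert (hx, hy, h) == (3.0, 3.0, 3.0)

    def test_symmetric_cherry(self):
        t = tree_from_newick("(a:2,b:2):1;")
        hx, hy, h = height_pair(t, ("a", "b"))
        assert hx == hy == h == 2.0

    def test_non_reducible_pair_raises(self, cherry_network):
        with pytest.raises(ValueError):
            height_pair(cherry_network, ("x", "z"))


class TestCounts:
    def test_tree_has_no_reticulations(self):
        assert tree_from_newick("((a,b),c);").reticulation_number() == 0

    def test_example_networks(self, example_network):
        assert example_network.reticulation_number() == 1
        n2 = network_from_cps(
            CherrySeq([("w", "x"), ("y", "z"), ("y", "x"), ("w", "x"), ("x", "z")])
        )
        assert n2.reticulation_number() == 2

    def test_node_count_identity_preserved_by_moves(self):
        net = generate_lgt(6, 3, seed=5)
        for pair in reducible_pairs(net):
            red, _ = reduce_pair(net, pair)

            def tree_nodes(n):
                return sum(
                    1
                    for v in n.nodes()
                    if n.in_degree(v) == 1 and n.out_degree(v) == 2
                )

            assert tree_nodes(red) == red.num_leaves() + red.reticulation_number() - 1


# ---------------------------------------------------------------- displays
def _clusters(tree, taxa=None):
    """Set of leaf clusters of each node, optionally restricted to *taxa*."""
    out = set()

    def below(v):
        lab = tree.label_of(v)
        if lab is not None:
            return frozenset([lab])
        s = frozenset()
        for c in tree.children(v):
            s |= below(c)
        return s

    for v in tree.nodes():
        s = below(v)
        if taxa is not None:
            s = frozenset(s & taxa)
        if s:
            out.add(s)
    return out


def _displays_by_clusters(net, tree):
    """Independent display oracle: recursive switching + cluster-set equality."""
    target = _clusters(tree)
    taxa = tree.leaves
    retics = [v for v in net.nodes() if net.is_reticulation(v)]

    def rec(i, removed):
        if i == len(retics):
            work = net.copy()
            for u, v in removed:
                work.remove_edge(u, v)
            return _restricted_clusters(work, taxa) == target
        v = retics[i]
        for p in net.parents(v):
            others = [(q, v) for q in net.parents(v) if q != p]
            if rec(i + 1, removed + others):
                return True
        return False

    return rec(0, [])


def _restricted_clusters(net, taxa):
    out = set()
    memo = {}

    def below(v):
        if v in memo:
            return memo[v]
        lab = net.label_of(v)
        if lab is not None:
            memo[v] = frozenset([lab]) if lab in taxa else frozenset()
        else:
            s = frozenset()
            for c in net.children(v):
                s |= below(c)
            memo[v] = s
        return memo[v]

    for v in net.nodes():
        s = below(v)
        if s:
            out.add(s)
    return out


class TestDisplays:
    def test_example_trees_are_displayed(self, example_network, example_trees):
        for t in example_trees:
            assert displays(example_network, t)

    def test_tree_displays_itself(self):
        t = tree_from_newick("(((a,b),c),d);")
        assert displays(t, t)

    def test_caterpillar_leaf_swap_not_displayed(self):
        a = tree_from_newick("(((a,b),c),d);")
        b = tree_from_newick("(((a,c),b),d);")
        assert not displays(a, b)
        assert not displays(b, a)

    def test_subset_leaf_restriction(self, example_network, example_trees):
        small = restrict_tree(example_trees[0], {"x", "y", "z"})
        assert displays(example_network, small)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_independent_cluster_oracle(self, seed):
        rng = random.Random(seed)
        net = generate_lgt(
            rng.randint(4, 6), rng.randint(1, 3), seed=rng.randrange(2**31)
        )
        # probe with displayed trees of this and of another network
        from cphnet.simgen import exhaustive_trees

        probes = exhaustive_trees(net)[:2]
        other = generate_lgt(net.num_leaves(), 1, seed=seed + 1000)
        relabel = {f"t{i+1}" for i in range(net.num_leaves())}
        probes += [t for t in exhaustive_trees(other)[:2] if t.leaves == relabel]
        for t in probes:
            assert displays(net, t) == _displays_by_clusters(net, t)


class TestCanonicalForm:
    def test_canonical_ignores_child_order(self):
        a = tree_from_newick("((a,b),c);")
        b = tree_from_newick("(c,(b,a));")
        assert tree_canonical(a) == tree_canonical(b)
        assert isomorphic(a, b)

    def test_different_topologies_differ(self):
        a = tree_from_newick("((a,b),c);")
        b = tree_from_newick("((a,c),b);")
        assert tree_canonical(a) != tree_canonical(b)
        assert not isomorphic(a, b)
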