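"""The CPH loop, sequence completion, pickers and tree expansion."""

from __future__ import annotations

import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cphnet.cps import (
    CherrySeq,
    LowPairPicker,
    Picker,
    PickerContractError,
    RandPicker,
    TreeSetState,
    TrivialRandPicker,
    complete_seq,
    run_best_of,
    run_cph,
    run_heuristic,
)
from cphnet.io import tree_from_newick
from cphnet.phylo import PhyloTree, displays, tree_canonical
from cphnet.reconstruct import expected_reticulations, network_from_cps
from cphnet.simgen import generate_lgt, sample_displayed_trees


def _trees(*newicks):
    return [tree_from_newick(s) for s in newicks]


class TestCompleteSeq:
    def test_worked_example(self):
        out = complete_seq(CherrySeq([("x", "y"), ("w", "z")]))
        assert out.pairs == [("x", "y"), ("w", "z"), ("y", "z")]
        assert out.is_valid_cps()

    def test_complete_sequence_is_fixed_point(self):
        s = CherrySeq([("x", "y"), ("y", "z")])
        assert s.is_valid_cps()
        assert complete_seq(s).pairs == s.pairs

    def test_three_disjoint_cherries(self):
        out = complete_seq(CherrySeq([("a", "b"), ("c", "d"), ("e", "f")]))
        assert out.is_valid_cps()
        assert out.pairs[:3] == [("a", "b"), ("c", "d"), ("e", "f")]

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from("abcdefg"), st.sampled_from("abcdefg")
            ).filter(lambda p: p[0] != p[1]),
            min_size=1,
            max_size=12,
        )
    )
    def test_completion_of_arbitrary_pair_list_is_valid(self, pairs):
        out = complete_seq(CherrySeq(pairs))
        assert out.pairs[: len(pairs)] == pairs
        assert out.is_valid_cps()
        # appended pairs only mention taxa already seen
        seen = {t for p in pairs for t in p}
        assert {t for p in out.pairs for t in p} == seen


class TestRunCph:
    def test_single_cherry_tree(self):
        seq = run_heuristic([PhyloTree.from_cherry("x", "y")],
                            lambda s: RandPicker(random.Random(s)), seed=0)
        assert len(seq) == 1 and seq[0] in (("x", "y"), ("y", "x"))

    def test_output_is_cps_and_reduces_inputs(self):
        trees = _trees("((a,b),(c,d));", "(((a,c),b),d);", "((a,b),c);")
        for seed in range(5):
            seq = run_heuristic(trees, lambda s: RandPicker(random.Random(s)),
                                seed=seed)
            assert seq.is_valid_cps()
            assert seq.fully_reduces(trees)

    def test_sequence_length_bound(self):
        net = generate_lgt(8, 3, seed=3)
        trees = sample_displayed_trees(net, 4, seed=1)
        for seed in range(5):
            seq = run_heuristic(trees, lambda s: TrivialRandPicker(random.Random(s)),
                                seed=seed)
            n_taxa = len({t for tr in trees for t in tr.leaves})
            assert len(seq) <= (n_taxa - 1) * len(trees)

    def test_bad_picker_raises(self):
        class Bad(Picker):
            def pick(self, state):
                return ("nope", "nada")

        with pytest.raises(PickerContractError):
            run_cph(TreeSetState(_trees("((a,b),c);")), Bad())

    def test_best_of_is_deterministic_and_no_worse(self):
        net = generate_lgt(8, 4, seed=9)
        trees = sample_displayed_trees(net, 4, seed=2)
        factory = lambda s: TrivialRandPicker(random.Random(s))
        one = run_best_of(trees, factory, n_runs=1, seed=5)
        best = run_best_of(trees, factory, n_runs=20, seed=5)
        again = run_best_of(trees, factory, n_runs=20, seed=5)
        assert best.pairs == again.pairs
        assert expected_reticulations(best) <= expected_reticulations(one)


class TestPickers:
    def test_single_pair_is_returned(self):
        state = TreeSetState(_trees("((a,b),c);"))
        assert RandPicker(random.Random(0)).pick(state) in (("a", "b"), ("b", "a"))

    def test_rand_is_uniform(self):
        state = TreeSetState(_trees("((a,b),(c,d));"))
        picker = RandPicker(random.Random(42))
        counts = Counter(picker.pick(state) for _ in range(10000))
        assert set(counts) == {("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")}
        p = stats.chisquare(list(counts.values())).pvalue
        assert p > 1e-3

    def test_lowpair_prefers_low_mean_height(self):
        # (a,b) heights 1 and 3 in two trees (mean 2); (c,d) height 4
        trees = _trees("((a:1,b:1):1,(c:4,d:4):1):1;", "((a:3,b:3):1,e:1):1;")
        state = TreeSetState(trees)
        assert LowPairPicker(random.Random(0)).pick(state) in (("a", "b"), ("b", "a"))

    def test_lowpair_breaks_ties_uniformly(self):
        trees = _trees("((a:1,b:1):1,(c:1,d:1):1):1;")
        state = TreeSetState(trees)
        picker = LowPairPicker(random.Random(3))
        counts = Counter(picker.pick(state) for _ in range(4000))
        assert len(counts) == 4
        p = stats.chisquare(list(counts.values())).pvalue
        assert p > 1e-3

    def test_trivialrand_prefers_trivial(self):
        # trivial pairs: (a,b) (cherry wherever both occur) and (d,e)
        # (tree 1 lacks e); (c,d) occurs in both trees but is a cherry in
        # only one, so it must never be picked while trivial pairs exist
        trees = _trees("((a,b),(c,d));", "((c,(d,e)),(a,b));")
        state = TreeSetState(trees)
        assert set(state.trivial_pairs()) == {
            ("a", "b"), ("b", "a"), ("d", "e"), ("e", "d")
        }
        picker = TrivialRandPicker(random.Random(0))
        for _ in range(50):
            assert picker.pick(state) in state.trivial_pairs()


class TestTrivialPairs:
    def test_every_cherry_of_a_single_tree_is_trivial(self):
        state = TreeSetState(_trees("((a,b),(c,d));"))
        assert set(state.trivial_pairs()) == set(state.cherry_trees)

    def test_non_cherry_occurrence_blocks_trivialness(self):
        trees = _trees("((a,b),c);", "((a,c),b);")
        state = TreeSetState(trees)
        assert not state.is_trivial(("a", "b"))

    def test_missing_leaf_does_not_block_trivialness(self):
        # (a,b) cherry in tree 1; tree 2 lacks b entirely (type iv)
        trees = _trees("((a,b),c);", "((a,d),c);")
        state = TreeSetState(trees)
        assert state.is_trivial(("a", "b"))


class TestTreeExpansion:
    def test_type_iv_tree_gets_the_cherry(self):
        trees = _trees("((a,b),c);", "((a,d),c);")
        state = TreeSetState(trees)
        assert state.tree_expand(("a", "b")) == 1
        t2 = state.trees[1]
        assert t2.classify_pair(("a", "b")).name == "CHERRY"

    def test_no_type_iv_trees_is_noop(self):
        trees = _trees("((a,b),c);", "((a,b),d);")
        state = TreeSetState(trees)
        assert state.tree_expand(("a", "b")) == 0

    def test_expansion_plus_reduction_equals_relabelling(self):
        trees = _trees("((a,b),c);", "((a,d),c);")
        state = TreeSetState(trees)
        state.tree_expand(("a", "b"))
        state.reduce(("a", "b"))
        relabelled = tree_from_newick("((b,d),c);")
        assert tree_canonical(state.trees[1]) == tree_canonical(relabelled)

    def test_non_trivial_pair_raises(self):
        trees = _trees("((a,b),c);", "((a,c),b);")
        with pytest.raises(ValueError):
            TreeSetState(trees).tree_expand(("a", "b"))

    def test_expansion_network_displays_original_trees(self):
        # end-to-end: trees with differing leaf sets, expansion enabled
        net = generate_lgt(5, 2, seed=21)
        trees = sample_displayed_trees(net, 3, seed=4)
        from cphnet.simgen import remove_leaves

        trees = remove_leaves(trees, 20.0, seed=1)
        for seed in range(5):
            seq = run_heuristic(
                trees, lambda s: TrivialRandPicker(random.Random(s)),
                seed=seed, expansion=True,
            )
            out = network_from_cps(seq)
            for t in trees:
                assert displays(out, t)


class TestBranchLengthConservation:
    def test_root_to_leaf_distance_preserved_by_reduction(self):
        t = tree_from_newick("((a:1,b:2):3,(c:4,d:5):6):7;")

        def depth(tree, taxon):
            v = tree.leaf_node(taxon)
            d = 0.0
            while v != tree.root:
                p = tree.parent(v)
                d += tree.length(p, v)
                v = p
            return d

        before = {x: depth(t, x) for x in "bcd"}
        t.reduce_pair(("a", "b"))
        after = {x: depth(t, x) for x in "bcd"}
        assert before == after
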