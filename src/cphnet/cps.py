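"""The cherry-picking heuristic loop and its randomised pickers.

The CPH loop repeatedly picks an ordered pair that is a cherry in at least
one of the (partially reduced) input trees, appends it to a growing partial
sequence and reduces it in every tree, until all trees are down to a single
leaf.  The partial sequence is then completed into a proper cherry-picking
sequence (every second element reappears later as a first element, except in
the final pair) by appending pairs that no longer affect the trees.

Pickers implemented here:

* ``RandPicker`` — uniform over the current reducible pairs.
* ``LowPairPicker`` — lowest mean height over the trees where the pair is
  reducible (ties broken uniformly at random); requires branch lengths.
* ``TrivialRandPicker`` — a uniformly random *trivial* pair when one exists
  (a pair reducible in every tree containing both leaves), otherwise uniform
  random; combined by default with tree expansion.

Tree expansion: before reducing a trivial pair (x, y), every tree containing
x but not y has its leaf x replaced by the cherry (x, y), so that x vanishes
from the whole tree set after the reduction.  This is equivalent to
relabelling x as y in those trees and preserves displayability of the
original trees in the reconstructed network.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .phylo import Pair, PhyloTree


class PickerContractError(RuntimeError):
    """A picker returned a pair that is not currently reducible."""


@dataclass
class CherrySeq:
    """An ordered list of leaf pairs (partial or complete CPS)."""

    pairs: List[Pair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def taxa(self) -> Set[str]:
        out: Set[str] = set()
        for x, y in self.pairs:
            out.add(x)
            out.add(y)
        return out

    def is_valid_cps(self) -> bool:
        """Check the defining property: y_i in {x_{i+1},...,x_n, y_n}."""
        n = len(self.pairs)
        later_firsts: Set[str] = set()
        ok = True
        for i in range(n - 1, -1, -1):
            x, y = self.pairs[i]
            if i < n - 1 and y not in later_firsts and y != self.pairs[-1][1]:
                ok = False
                break
            later_firsts.add(x)
        return ok

    def fully_reduces(self, trees: Sequence[PhyloTree]) -> bool:
        for t in trees:
            c = t.copy()
            for pair in self.pairs:
                c.reduce_pair(pair)
            if not c.is_fully_reduced():
                return False
        return True


def complete_seq(partial: CherrySeq) -> CherrySeq:
    """Append pairs turning a partial sequence into a proper CPS.

    Second elements with no later occurrence as a first element are chained
    in sorted order: (d1,d2),(d2,d3),...  The appended pairs involve only
    already-reduced leaves, so they do not affect the trees.  Linear time.
    """
    pairs = list(partial.pairs)
    if not pairs:
        return CherrySeq([])
    seen_first: Set[str] = set()
    unresolved: Set[str] = set()
    for x, y in reversed(pairs):
        if y not in seen_first:
            unresolved.add(y)
        seen_first.add(x)
    chain = sorted(unresolved)
    for a, b in zip(chain, chain[1:]):
        pairs.append((a, b))
    return CherrySeq(pairs)


class TreeSetState:
    """A set of partially reduced trees with incremental cherry bookkeeping.

    Maintains, after every reduction/expansion:

    * ``cherry_trees`` — ordered pair -> ids of trees where it is currently a
      cherry (both orders are stored);
    * ``leaf_trees`` — taxon -> ids of active trees containing that leaf;
    * ``tree_cherries`` — tree id -> set of unordered cherry pairs;
    * ``active`` — ids of trees not yet fully reduced.
    """

    def __init__(self, trees: Sequence[PhyloTree], seed: int = 0) -> None:
        self.trees: Dict[int, PhyloTree] = {i: t.copy() for i, t in enumerate(trees)}
        self.rng = random.Random(seed)
        self.active: Set[int] = set()
        self.cherry_trees: Dict[Pair, Set[int]] = {}
        self.leaf_trees: Dict[str, Set[int]] = {}
        self.tree_cherries: Dict[int, Set[frozenset]] = {}
        for tid, t in self.trees.items():
            self.tree_cherries[tid] = set()
            if t.num_leaves() < 2:
                continue
            self.active.add(tid)
            for taxon in t.leaves:
                self.leaf_trees.setdefault(taxon, set()).add(tid)
            for node in list(t.nodes()):
                cs = t.children(node)
                if len(cs) == 2 and t.is_leaf(cs[0]) and t.is_leaf(cs[1]):
                    a, b = t.label_of(cs[0]), t.label_of(cs[1])
                    self._register_cherry(tid, a, b)

    # --------------------------------------------------------------- helpers
    def _register_cherry(self, tid: int, a: str, b: str) -> None:
        self.cherry_trees.setdefault((a, b), set()).add(tid)
        self.cherry_trees.setdefault((b, a), set()).add(tid)
        self.tree_cherries[tid].add(frozenset((a, b)))

    def _unregister_cherry(self, tid: int, a: str, b: str) -> None:
        for key in ((a, b), (b, a)):
            s = self.cherry_trees.get(key)
            if s is not None:
                s.discard(tid)
                if not s:
                    del self.cherry_trees[key]
        self.tree_cherries[tid].discard(frozenset((a, b)))

    def _drop_leaf(self, tid: int, taxon: str) -> None:
        s = self.leaf_trees.get(taxon)
        if s is not None:
            s.discard(tid)
            if not s:
                del self.leaf_trees[taxon]

    def both_trees(self, pair: Pair) -> Set[int]:
        """Active trees containing both leaves of the pair."""
        a = self.leaf_trees.get(pair[0])
        b = self.leaf_trees.get(pair[1])
        if not a or not b:
            return set()
        return a & b

    def is_trivial(self, pair: Pair) -> bool:
        ct = self.cherry_trees.get(pair)
        if not ct:
            return False
        return ct >= self.both_trees(pair)

    def trivial_pairs(self) -> List[Pair]:
        return [p for p in self.cherry_trees if self.is_trivial(p)]

    def total_cherries(self) -> int:
        """Number of (unordered cherry, tree) incidences in the current set."""
        return sum(len(c) for c in self.tree_cherries.values())

    def num_active(self) -> int:
        return len(self.active)

    # ------------------------------------------------------------ operations
    def reduce(self, pair: Pair) -> int:
        """Reduce *pair* in every tree where it is a cherry; return count."""
        x, y = pair
        tids = self.cherry_trees.get(pair)
        if not tids:
            return 0
        affected = 0
        for tid in sorted(tids):
            t = self.trees[tid]
            self._unregister_cherry(tid, x, y)
            t.reduce_pair((x, y))
            affected += 1
            self._drop_leaf(tid, x)
            if t.is_fully_reduced():
                self.active.discard(tid)
                self._drop_leaf(tid, y)
                continue
            yn = t.leaf_node(y)
            p = t.parent(yn)
            for c in t.children(p):
                if c != yn and t.is_leaf(c):
                    self._register_cherry(tid, y, t.label_of(c))
        return affected

    def tree_expand(self, pair: Pair) -> int:
        """Replace leaf x by cherry (x, y) in trees with x but not y."""
        x, y = pair
        if not self.is_trivial(pair):
            raise ValueError(f"pair {pair} is not trivial")
        targets = [
            tid
            for tid in self.leaf_trees.get(x, set())
            if tid not in self.leaf_trees.get(y, set())
        ]
        for tid in targets:
            t = self.trees[tid]
            xn = t.leaf_node(x)
            p = t.parent(xn)
            for c in t.children(p):
                if c != xn and t.is_leaf(c):
                    self._unregister_cherry(tid, x, t.label_of(c))
            t.expand_leaf(x, y)
            self.leaf_trees.setdefault(y, set()).add(tid)
            self._register_cherry(tid, x, y)
        return len(targets)


# ------------------------------------------------------------------- pickers
class Picker:
    """PickNext strategy; subclasses implement :meth:`pick`."""

    wants_expansion = False

    def reset(self, state: TreeSetState) -> None:  # pragma: no cover - hook
        pass

    def after_step(self, state: TreeSetState, pair: Pair) -> None:  # hook
        pass

    def pick(self, state: TreeSetState) -> Pair:
        raise NotImplementedError


class RandPicker(Picker):
    """Uniform over the current ordered reducible pairs."""

    def __init__(self, rng: Optional[random.Random] = None) -> None:
        self.rng = rng

    def _rng(self, state: TreeSetState) -> random.Random:
        return self.rng if self.rng is not None else state.rng

    def pick(self, state: TreeSetState) -> Pair:
        keys = list(state.cherry_trees)
        if not keys:
            raise PickerContractError("no reducible pair available")
        return keys[self._rng(state).randrange(len(keys))]


class LowPairPicker(RandPicker):
    """Lowest mean height over the trees where the pair is reducible."""

    def pick(self, state: TreeSetState) -> Pair:
        best: List[Pair] = []
        best_h = None
        for pair, tids in state.cherry_trees.items():
            total = 0.0
            for tid in tids:
                hx, hy = state.trees[tid].height_pair(pair)
                total += (hx + hy) / 2.0
            h = total / len(tids)
            if best_h is None or h < best_h:
                best_h, best = h, [pair]
            elif h == best_h:
                best.append(pair)
        if not best:
            raise PickerContractError("no reducible pair available")
        return best[self._rng(state).randrange(len(best))]


class TrivialRandPicker(RandPicker):
    """A uniformly random trivial pair when one exists, else uniform random."""

    wants_expansion = True

    def pick(self, state: TreeSetState) -> Pair:
        trivial = state.trivial_pairs()
        if trivial:
            return trivial[self._rng(state).randrange(len(trivial))]
        return super().pick(state)


# ------------------------------------------------------------------ the loop
def run_cph(
    state: TreeSetState,
    picker: Picker,
    expansion: Optional[bool] = None,
) -> CherrySeq:
    """Run the cherry-picking heuristic loop and return a complete CPS.

    *expansion* defaults to the picker's preference; when enabled, tree
    expansion is applied whenever the picked pair is trivial.
    """
    if expansion is None:
        expansion = picker.wants_expansion
    picker.reset(state)
    seq: List[Pair] = []
    while state.cherry_trees:
        pair = picker.pick(state)
        if pair not in state.cherry_trees:
            raise PickerContractError(f"picker returned non-reducible pair {pair}")
        if expansion and state.is_trivial(pair):
            state.tree_expand(pair)
        seq.append(pair)
        state.reduce(pair)
        picker.after_step(state, pair)
    return complete_seq(CherrySeq(seq))


def run_heuristic(
    trees: Sequence[PhyloTree],
    picker_factory: Callable[[int], Picker],
    seed: int = 0,
    expansion: Optional[bool] = None,
) -> CherrySeq:
    """Build a fresh state from *trees* and run one heuristic pass."""
    state = TreeSetState(trees, seed=seed)
    return run_cph(state, picker_factory(seed), expansion=expansion)


def run_best_of(
    trees: Sequence[PhyloTree],
    picker_factory: Callable[[int], Picker],
    n_runs: int,
    seed: int = 0,
    expansion: Optional[bool] = None,
) -> CherrySeq:
    """Best of *n_runs* seeded runs, judged by the implied reticulation
    number |S| - |X| + 1 (fewest wins; first winner kept on ties)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = random.Random(seed)
    seeds = [root.randrange(2**31) for _ in range(n_runs)]
    best_seq: Optional[CherrySeq] = None
    best_r: Optional[int] = None
    for s in seeds:
        seq = run_heuristic(trees, picker_factory, seed=s, expansion=expansion)
        r = len(seq) - len(seq.taxa()) + 1
        if best_r is None or r < best_r:
            best_r, best_seq = r, seq
    assert best_seq is not None
    return best_seq
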