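"""Rebuilding the orchard network for which a CPS is minimum-length.

Pairs are added in reverse order: a first element not yet in the network is
attached as a cherry with the second element; a first element already present
gets a reticulation above it, fed from a new parent subdividing the edge
above the second element.  The reconstructed network is fully reduced by the
sequence, displays every tree the sequence fully reduces, and carries no
meaningful branch lengths (placeholders are flagged synthetic).

The number of reticulations of the reconstruction equals |S| - |X| + 1.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .cps import CherrySeq, complete_seq
from .phylo import (
    InvalidSequenceError,
    Pair,
    PhyloNetwork,
    PhyloTree,
    ResourceError,
    tree_canonical,
)


def network_from_cps(seq: CherrySeq) -> PhyloNetwork:
    """Reconstruct the unique binary orchard network reduced by *seq*."""
    pairs = list(seq)
    if not pairs:
        raise InvalidSequenceError("cannot reconstruct from an empty sequence")
    net = PhyloNetwork()
    net.synthetic_lengths = True
    for pair in reversed(pairs):
        net.add_pair(pair)
    net.validate()
    return net


def expected_reticulations(seq: CherrySeq) -> int:
    """|S| - |X| + 1 — the reticulation count of the reconstruction."""
    return len(seq) - len(seq.taxa()) + 1


def min_cps_oracle(
    trees: Sequence[PhyloTree],
    max_len: int = 16,
) -> CherrySeq:
    """Exhaustive search for a shortest complete CPS fully reducing *trees*.

    Iterative deepening over the total (completed) length.  The unresolved
    second elements of a partial sequence are tracked forward (appending
    (x, y) resolves x and adds y), so the completion cost of a partial
    sequence is max(0, |unresolved| - 1).  Intended for tiny instances only.
    """
    taxa: Set[str] = set()
    for t in trees:
        taxa |= t.leaves
    if len(taxa) > 6 or len(trees) > 5:
        raise ResourceError("oracle restricted to <=6 taxa and <=5 trees")

    base = [t.copy() for t in trees if t.num_leaves() >= 2]
    if not base:
        return CherrySeq([])

    def state_key(ts: Sequence[PhyloTree]) -> Tuple[str, ...]:
        return tuple(sorted(tree_canonical(t) for t in ts))

    def reducible(ts: Sequence[PhyloTree]) -> List[Pair]:
        out: Set[Pair] = set()
        for t in ts:
            for node in t.nodes():
                cs = t.children(node)
                if len(cs) == 2 and t.is_leaf(cs[0]) and t.is_leaf(cs[1]):
                    a, b = t.label_of(cs[0]), t.label_of(cs[1])
                    out.add((a, b))
                    out.add((b, a))
        return sorted(out)

    def lower_bound(ts: Sequence[PhyloTree]) -> int:
        return max((t.num_leaves() - 1 for t in ts), default=0)

    for target in range(lower_bound(base), max_len + 1):
        visited: Dict[Tuple[Tuple[str, ...], FrozenSet[str]], int] = {}
        result: Optional[List[Pair]] = None

        def dfs(
            ts: List[PhyloTree],
            unresolved: FrozenSet[str],
            partial: List[Pair],
        ) -> bool:
            nonlocal result
            live = [t for t in ts if not t.is_fully_reduced()]
            if not live:
                total = len(partial) + max(0, len(unresolved) - 1)
                if total <= target:
                    result = list(partial)
                    return True
                return False
            if len(partial) + lower_bound(live) > target:
                return False
            key = (state_key(live), unresolved)
            prev = visited.get(key)
            if prev is not None and prev <= len(partial):
                return False
            visited[key] = len(partial)
            for pair in reducible(live):
                nxt = [t.copy() for t in ts]
                for t in nxt:
                    t.reduce_pair(pair)
                u = (unresolved - {pair[0]}) | {pair[1]}
                partial.append(pair)
                if dfs(nxt, frozenset(u), partial):
                    return True
                partial.pop()
            return False

        if dfs(base, frozenset(), []):
            assert result is not None
            return complete_seq(CherrySeq(result))
    raise ResourceError(f"no CPS of completed length <= {max_len} found")
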