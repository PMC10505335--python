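"""The 19 cherry features guiding the learned and feature-based pickers.

For an ordered candidate pair (x, y) of the current tree set:

1.  cherry-in-tree — fraction of active trees in which (x, y) is a cherry;
2.  new cherries — number of (tree, pair) cherry incidences created by
    picking (x, y);
3.  before/after — ratio of the number of cherry incidences before vs after
    picking (x, y);
4.  trivial — fraction of trees containing both x and y in which (x, y) is a
    cherry (1.0 exactly for trivial pairs);
5.  leaves-in-tree — fraction of active trees containing both x and y;
6-12. depth/distance summaries, each in a branch-length (``d``) and a
    topological (``t``) variant: relative tree depth, relative cherry depth,
    scaled x-y leaf distance, scaled root-to-x and root-to-y depths, the
    x-vs-y distance ratio to their LCA, and the root-distance ratio x/y.

The depth of a tree is the maximum depth of any of its cherries; the leaf
distance of a cherry is zero.  Averages over an empty tree subset, and ratios
with a zero denominator, contribute 0.0 so that feature vectors are total.

Feature vectors are evaluated on demand from the incremental indexes of
:class:`~cphnet.cps.TreeSetState` plus per-tree depth caches that are
invalidated by the trees' version stamps, so an evaluation after any number
of reductions equals a from-scratch recomputation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cps import TreeSetState
from .phylo import Pair, PhyloTree

FEATURE_NAMES: List[str] = (
    ["f1", "f2", "f3", "f4", "f5"]
    + [f"f{i}{m}" for i in range(6, 13) for m in ("d", "t")]
)

_D = 0  # branch-length metric index
_T = 1  # topological metric index


class _TreeInfo:
    """Per-tree cache: node depths (both metrics) and the tree depth."""

    __slots__ = ("version", "depth_d", "depth_t", "tree_depth")

    def __init__(self, tree: PhyloTree, cherries) -> None:
        self.version = tree.version
        self.depth_d: Dict[int, float] = {}
        self.depth_t: Dict[int, int] = {}
        stack = [(tree.root, 0.0, 0)]
        while stack:
            v, dd, dt = stack.pop()
            self.depth_d[v] = dd
            self.depth_t[v] = dt
            for c in tree.children(v):
                stack.append((c, dd + tree.length(v, c), dt + 1))
        # tree depth = max depth of any cherry (parent of a cherry pair)
        best_d, best_t = 0.0, 0
        for pair in cherries:
            a = next(iter(pair))
            p = tree.parent(tree.leaf_node(a))
            best_d = max(best_d, self.depth_d[p])
            best_t = max(best_t, self.depth_t[p])
        self.tree_depth = (best_d, best_t)


class FeatureIndex:
    """Feature evaluation over a (reducing) :class:`TreeSetState`."""

    def __init__(self, state: TreeSetState) -> None:
        self.state = state
        self._info: Dict[int, _TreeInfo] = {}

    # ------------------------------------------------------------- caching
    def _tree_info(self, tid: int) -> _TreeInfo:
        tree = self.state.trees[tid]
        info = self._info.get(tid)
        if info is None or info.version != tree.version:
            info = _TreeInfo(tree, self.state.tree_cherries[tid])
            self._info[tid] = info
        return info

    def _global_max_depth(self) -> Tuple[float, int]:
        best_d, best_t = 0.0, 0
        for tid in self.state.active:
            d, t = self._tree_info(tid).tree_depth
            best_d = max(best_d, d)
            best_t = max(best_t, t)
        return best_d, best_t

    # ---------------------------------------------------------- evaluation
    def features_for(self, pair: Pair) -> np.ndarray:
        state = self.state
        x, y = pair
        cherry_tids = state.cherry_trees.get(pair, set())
        both_tids = state.both_trees(pair)
        n_active = state.num_active()
        vec = np.zeros(len(FEATURE_NAMES))

        vec[0] = len(cherry_tids) / n_active if n_active else 0.0
        vec[4] = len(both_tids) / n_active if n_active else 0.0
        vec[3] = len(cherry_tids) / len(both_tids) if both_tids else 0.0

        # f2: cherry incidences created by picking (x, y); a new cherry
        # appears in a tree when, after removing x, y's new sibling is a leaf
        new_cherries = 0
        for tid in cherry_tids:
            t = state.trees[tid]
            p = t.parent(t.leaf_node(x))
            ps = t.parents(p)
            if not ps:
                continue
            g = ps[0]
            if g == t.root:
                continue
            for c in t.children(g):
                if c != p and t.is_leaf(c):
                    new_cherries += 1
        vec[1] = new_cherries
        before = state.total_cherries()
        after = before - len(cherry_tids) + new_cherries
        vec[2] = before / after if after > 0 else 0.0

        gmax = self._global_max_depth()
        # averages over trees where (x, y) is a cherry: f6, f7
        if cherry_tids:
            for m, depth_attr in ((_D, "depth_d"), (_T, "depth_t")):
                s6 = s7 = 0.0
                for tid in cherry_tids:
                    info = self._tree_info(tid)
                    td = info.tree_depth[m]
                    cherry_depth = getattr(info, depth_attr)[
                        state.trees[tid].parent(state.trees[tid].leaf_node(x))
                    ]
                    s6 += td / gmax[m] if gmax[m] else 0.0
                    s7 += cherry_depth / td if td else 0.0
                vec[5 + m] = s6 / len(cherry_tids)
                vec[7 + m] = s7 / len(cherry_tids)

        # averages over trees containing both x and y: f8..f12
        if both_tids:
            sums = np.zeros((5, 2))  # rows: f8..f12; cols: d, t
            for tid in both_tids:
                t = state.trees[tid]
                info = self._tree_info(tid)
                xn, yn = t.leaf_node(x), t.leaf_node(y)
                lca = self._lca(t, info, xn, yn)
                for m, depth in ((_D, info.depth_d), (_T, info.depth_t)):
                    td = info.tree_depth[m]
                    px, py = t.parent(xn), t.parent(yn)
                    leafdist = (depth[px] - depth[lca]) + (depth[py] - depth[lca])
                    sums[0, m] += leafdist / td if td else 0.0
                    sums[1, m] += depth[xn] / td if td else 0.0
                    sums[2, m] += depth[yn] / td if td else 0.0
                    dy_lca = depth[yn] - depth[lca]
                    dx_lca = depth[xn] - depth[lca]
                    sums[3, m] += dx_lca / dy_lca if dy_lca else 0.0
                    sums[4, m] += depth[xn] / depth[yn] if depth[yn] else 0.0
            for row in range(5):
                for m in (0, 1):
                    vec[9 + 2 * row + m] = sums[row, m] / len(both_tids)
        return vec

    @staticmethod
    def _lca(tree: PhyloTree, info: _TreeInfo, u: int, v: int) -> int:
        du, dv = info.depth_t[u], info.depth_t[v]
        while du > dv:
            u = tree.parent(u)
            du -= 1
        while dv > du:
            v = tree.parent(v)
            dv -= 1
        while u != v:
            u = tree.parent(u)
            v = tree.parent(v)
        return u

    def table(
        self, pairs: Optional[Sequence[Pair]] = None
    ) -> Tuple[List[Pair], np.ndarray]:
        """Feature matrix for *pairs* (default: all current ordered cherries)."""
        if pairs is None:
            pairs = list(self.state.cherry_trees)
        if not pairs:
            return [], np.zeros((0, len(FEATURE_NAMES)))
        return list(pairs), np.vstack([self.features_for(p) for p in pairs])

    def frame(self, pairs: Optional[Sequence[Pair]] = None) -> pd.DataFrame:
        """Feature table as a DataFrame indexed by (first, second)."""
        pairs, mat = self.table(pairs)
        df = pd.DataFrame(mat, columns=FEATURE_NAMES)
        df.insert(0, "first", [p[0] for p in pairs])
        df.insert(1, "second", [p[1] for p in pairs])
        return df


def init_features(state: TreeSetState) -> FeatureIndex:
    """Build a feature index for a fresh tree-set state."""
    return FeatureIndex(state)


def update_features(
    index: FeatureIndex, reduced_pair: Pair
) -> FeatureIndex:
    """No-op hook kept for API symmetry: the index tracks the state lazily.

    The incremental bookkeeping lives in ``TreeSetState`` (cherry/leaf/tree
    indexes) and in the version-stamped per-tree caches of the index; after a
    reduction the next evaluation is automatically consistent.
    """
    return index
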