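"""Rooted binary phylogenetic trees and networks with cherry operations.

A network is a rooted DAG whose root has in-degree 0 and out-degree 1; every
other node is a tree node (in 1, out 2), a reticulation (in 2, out 1) or a
leaf (in 1, out 0).  Leaves carry unique taxon labels.  Edges may carry
nonnegative branch lengths; when the input provides none, every edge defaults
to 1.0 and the network is flagged as having synthetic lengths.

The two elementary moves of the cherry-picking framework live here:

* ``reduce_pair`` — picking a cherry deletes the first leaf and suppresses the
  resulting degree-2 node (branch lengths are summed); picking a reticulated
  cherry deletes the cross edge and suppresses the two degree-2 nodes.
* ``add_pair`` — the inverse move used to rebuild a network from a
  cherry-picking sequence: a new leaf is attached as a cherry with the second
  element, an existing leaf acquires a reticulation fed from a new parent of
  the second element.

A brute-force ``displays`` oracle (enumerating the 2^r reticulation
switchings) is provided for verification on small networks.
"""

from __future__ import annotations

import itertools
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx
from networkx.algorithms import isomorphism

Pair = Tuple[str, str]

DEFAULT_LENGTH = 1.0


class PairKind(Enum):
    CHERRY = "cherry"
    RETICULATED_CHERRY = "reticulated_cherry"
    NONE = "none"


class InvalidSequenceError(ValueError):
    """Raised when a cherry-picking sequence cannot be turned into a network."""


class ResourceError(RuntimeError):
    """Raised when an exhaustive oracle would exceed its enumeration budget."""


class PhyloNetwork:
    """Rooted binary phylogenetic network on labelled leaves.

    Nodes are opaque integers; use :meth:`leaf_node` to resolve a taxon.
    The structure is mutable: the cherry operations work in place and bump
    :attr:`version` so that external caches can detect staleness.
    """

    def __init__(self) -> None:
        self._children: Dict[int, List[int]] = {}
        self._parents: Dict[int, List[int]] = {}
        self._length: Dict[Tuple[int, int], float] = {}
        self._label: Dict[int, str] = {}
        self._leaf: Dict[str, int] = {}
        self.root: Optional[int] = None
        self._next = 0
        self.synthetic_lengths = False
        self.version = 0

    # ------------------------------------------------------------------ basic
    def new_node(self) -> int:
        v = self._next
        self._next += 1
        self._children[v] = []
        self._parents[v] = []
        return v

    def add_edge(self, u: int, v: int, length: float = DEFAULT_LENGTH) -> None:
        self._children[u].append(v)
        self._parents[v].append(u)
        self._length[(u, v)] = length

    def remove_edge(self, u: int, v: int) -> None:
        self._children[u].remove(v)
        self._parents[v].remove(u)
        del self._length[(u, v)]

    def remove_node(self, v: int) -> None:
        for u in list(self._parents[v]):
            self.remove_edge(u, v)
        for w in list(self._children[v]):
            self.remove_edge(v, w)
        del self._children[v]
        del self._parents[v]
        lab = self._label.pop(v, None)
        if lab is not None:
            del self._leaf[lab]
        if self.root == v:
            self.root = None

    def set_label(self, v: int, taxon: str) -> None:
        if taxon in self._leaf:
            raise ValueError(f"duplicate leaf label {taxon!r}")
        self._label[v] = taxon
        self._leaf[taxon] = v

    # ------------------------------------------------------------ inspection
    def nodes(self) -> Iterable[int]:
        return self._children.keys()

    def children(self, v: int) -> List[int]:
        return self._children[v]

    def parents(self, v: int) -> List[int]:
        return self._parents[v]

    def parent(self, v: int) -> int:
        ps = self._parents[v]
        if len(ps) != 1:
            raise ValueError(f"node {v} has {len(ps)} parents")
        return ps[0]

    def in_degree(self, v: int) -> int:
        return len(self._parents[v])

    def out_degree(self, v: int) -> int:
        return len(self._children[v])

    def is_leaf(self, v: int) -> bool:
        return not self._children[v] and v in self._label

    def is_reticulation(self, v: int) -> bool:
        return len(self._parents[v]) >= 2

    def label_of(self, v: int) -> Optional[str]:
        return self._label.get(v)

    def leaf_node(self, taxon: str) -> int:
        return self._leaf[taxon]

    @property
    def leaves(self) -> Set[str]:
        return set(self._leaf)

    def num_leaves(self) -> int:
        return len(self._leaf)

    def num_edges(self) -> int:
        return len(self._length)

    def length(self, u: int, v: int) -> float:
        return self._length[(u, v)]

    def edges(self) -> Iterable[Tuple[int, int]]:
        return self._length.keys()

    def reticulation_number(self) -> int:
        return sum(len(ps) - 1 for ps in self._parents.values() if len(ps) > 1)

    def is_fully_reduced(self) -> bool:
        """True when the network is a root with a single leaf (or empty)."""
        if self.root is None:
            return True
        if len(self._leaf) != 1:
            return False
        (child,) = self._children[self.root]
        return self.is_leaf(child)

    # ------------------------------------------------------------------ copy
    def copy(self) -> "PhyloNetwork":
        new = self.__class__()
        new._children = {v: list(cs) for v, cs in self._children.items()}
        new._parents = {v: list(ps) for v, ps in self._parents.items()}
        new._length = dict(self._length)
        new._label = dict(self._label)
        new._leaf = dict(self._leaf)
        new.root = self.root
        new._next = self._next
        new.synthetic_lengths = self.synthetic_lengths
        return new

    # -------------------------------------------------------------- validity
    def validate(self) -> None:
        """Raise ValueError if any structural invariant is broken."""
        if self.root is None:
            raise ValueError("network has no root")
        roots = [v for v in self._children if not self._parents[v]]
        if roots != [self.root] or self.out_degree(self.root) != 1:
            raise ValueError("root must be the unique in-degree-0 node with out-degree 1")
        n_tree = 0
        for v in self._children:
            din, dout = len(self._parents[v]), len(self._children[v])
            if v == self.root:
                continue
            if dout == 0:
                if din != 1 or v not in self._label:
                    raise ValueError(f"leaf {v} must have in-degree 1 and a label")
            elif din == 1 and dout == 2:
                n_tree += 1
            elif din == 2 and dout == 1:
                pass
            else:
                raise ValueError(f"node {v} has degrees ({din},{dout})")
        # acyclicity via DFS from root
        order = self._topo_order()
        if len(order) != len(self._children):
            raise ValueError("graph is not connected/acyclic from the root")
        r = self.reticulation_number()
        if self._leaf and n_tree != len(self._leaf) + r - 1:
            raise ValueError(
                f"tree-node count {n_tree} != |X| + r - 1 = {len(self._leaf) + r - 1}"
            )
        for e, l in self._length.items():
            if l < 0:
                raise ValueError(f"negative branch length on {e}")

    def _topo_order(self) -> List[int]:
        indeg = {v: len(ps) for v, ps in self._parents.items()}
        stack = [v for v, d in indeg.items() if d == 0]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            for w in self._children[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        return order

    # ------------------------------------------------------ cherry machinery
    def classify_pair(self, pair: Pair) -> PairKind:
        x, y = pair
        if x == y:
            return PairKind.NONE
        xn = self._leaf.get(x)
        yn = self._leaf.get(y)
        if xn is None or yn is None:
            return PairKind.NONE
        px = self._parents[xn][0]
        py = self._parents[yn][0]
        if px == py:
            return PairKind.CHERRY
        if len(self._parents[px]) == 2 and len(self._parents[py]) == 1:
            # p(x) is a reticulation; p(y) must be a tree-node parent of p(x)
            if py in self._parents[px]:
                return PairKind.RETICULATED_CHERRY
        return PairKind.NONE

    def _suppress(self, v: int) -> None:
        """Replace an in-1/out-1 node by a single edge, summing lengths."""
        (u,) = self._parents[v]
        (w,) = self._children[v]
        if (u, w) in self._length:
            raise ValueError("suppression would create a parallel edge")
        lu = self._length[(u, v)]
        lw = self._length[(v, w)]
        self.remove_edge(u, v)
        self.remove_edge(v, w)
        del self._children[v]
        del self._parents[v]
        self.add_edge(u, w, lu + lw)

    def reduce_pair(self, pair: Pair) -> bool:
        """Pick *pair* in place; return True iff the network was affected."""
        kind = self.classify_pair(pair)
        if kind is PairKind.NONE:
            return False
        x, y = pair
        xn = self._leaf[x]
        if kind is PairKind.CHERRY:
            p = self._parents[xn][0]
            self.remove_edge(p, xn)
            del self._children[xn]
            del self._parents[xn]
            del self._label[xn]
            del self._leaf[x]
            self._suppress(p)
        else:  # reticulated cherry
            ret = self._parents[xn][0]  # the reticulation above x
            py = self._parents[self._leaf[y]][0]
            # delete the cross edge (p(y), p(x)); both endpoints become unary
            self.remove_edge(py, ret)
            self._suppress(ret)
            self._suppress(py)
        self.version += 1
        return True

    def add_pair(self, pair: Pair) -> None:
        """Add *pair* back, the reverse of :meth:`reduce_pair` (topologically).

        Used to reconstruct a network from a cherry-picking sequence processed
        in reverse order: if the first element is absent it becomes a cherry
        with the second; otherwise a reticulation is created above the first
        element, fed from a new parent subdividing the edge above the second.
        """
        x, y = pair
        if x == y:
            raise InvalidSequenceError("pair elements must differ")
        if self.root is None:
            root = self.new_node()
            self.root = root
            p = self.new_node()
            xn = self.new_node()
            yn = self.new_node()
            self.add_edge(root, p)
            self.add_edge(p, xn)
            self.add_edge(p, yn)
            self.set_label(xn, x)
            self.set_label(yn, y)
            self.version += 1
            return
        yn = self._leaf.get(y)
        if yn is None:
            raise InvalidSequenceError(
                f"second element {y!r} absent from the growing network"
            )
        xn = self._leaf.get(x)
        if xn is None:
            # attach x as a cherry with y
            p = self._subdivide_above(yn)
            leaf = self.new_node()
            self.add_edge(p, leaf)
            self.set_label(leaf, x)
        else:
            ret = self._subdivide_above(xn)
            q = self._subdivide_above(yn)
            self.add_edge(q, ret)
        self.version += 1

    def _subdivide_above(self, v: int) -> int:
        u = self._parents[v][0]
        l = self._length[(u, v)]
        self.remove_edge(u, v)
        m = self.new_node()
        self.add_edge(u, m, l / 2.0)
        self.add_edge(m, v, l / 2.0)
        return m

    def height_pair(self, pair: Pair) -> Tuple[float, float]:
        """Branch-length coordinates (h_x, h_y) of a reducible pair."""
        kind = self.classify_pair(pair)
        if kind is PairKind.NONE:
            raise ValueError(f"pair {pair} is not reducible")
        x, y = pair
        xn, yn = self._leaf[x], self._leaf[y]
        if kind is PairKind.CHERRY:
            p = self._parents[xn][0]
            return self._length[(p, xn)], self._length[(p, yn)]
        py = self._parents[yn][0]
        px = self._parents[xn][0]
        return (
            self._length[(py, px)] + self._length[(px, xn)],
            self._length[(py, yn)],
        )

    def expand_leaf(self, x: str, y: str) -> None:
        """Replace leaf x by the cherry (x, y); new pendant edges get length 0.

        This is the tree-expansion move applied to trees that contain x but
        not y before a trivial pair (x, y) is reduced.
        """
        xn = self._leaf[x]
        if y in self._leaf:
            raise ValueError(f"{y!r} already present")
        del self._label[xn]
        del self._leaf[x]
        a = self.new_node()
        b = self.new_node()
        self.add_edge(xn, a, 0.0)
        self.add_edge(xn, b, 0.0)
        self.set_label(a, x)
        self.set_label(b, y)
        self.version += 1


class PhyloTree(PhyloNetwork):
    """A phylogenetic network with no reticulations."""

    def validate(self) -> None:
        super().validate()
        if self.reticulation_number() != 0:
            raise ValueError("tree has reticulations")

    @classmethod
    def from_cherry(cls, x: str, y: str) -> "PhyloTree":
        t = cls()
        t.add_pair((x, y))
        return t


# ------------------------------------------------------------------ functional
def classify_pair(net: PhyloNetwork, pair: Pair) -> PairKind:
    return net.classify_pair(pair)


def reduce_pair(net: PhyloNetwork, pair: Pair) -> Tuple[PhyloNetwork, bool]:
    """Non-mutating wrapper: returns (reduced copy, affected flag)."""
    out = net.copy()
    affected = out.reduce_pair(pair)
    return out, affected


def add_pair(net: PhyloNetwork, pair: Pair) -> PhyloNetwork:
    out = net.copy()
    out.add_pair(pair)
    return out


def height_pair(net: PhyloNetwork, pair: Pair) -> Tuple[float, float, float]:
    hx, hy = net.height_pair(pair)
    return hx, hy, (hx + hy) / 2.0


def reticulation_number(net: PhyloNetwork) -> int:
    return net.reticulation_number()


def reducible_pairs(net: PhyloNetwork) -> List[Pair]:
    """All ordered reducible pairs (cherries and reticulated cherries)."""
    out = []
    for x, xn in net._leaf.items():
        p = net._parents[xn][0]
        if len(net._parents[p]) <= 1:
            # p is a tree node: sibling leaves form cherries with x
            for c in net._children[p]:
                if c != xn and net.is_leaf(c):
                    out.append((x, net._label[c]))
        else:
            # p is a reticulation: each tree-node parent of p with a leaf
            # child y yields a reticulated cherry (x, y)
            for q in net._parents[p]:
                if len(net._parents[q]) != 1:
                    continue
                for c in net._children[q]:
                    if net.is_leaf(c):
                        out.append((x, net._label[c]))
    return out


# ---------------------------------------------------------------- tree canon
def tree_canonical(tree: PhyloNetwork) -> str:
    """Canonical string of a rooted leaf-labelled tree (unary chains collapsed)."""
    if tree.root is None:
        return ""

    def canon(v: int) -> str:
        cs = tree._children[v]
        while len(cs) == 1:
            v = cs[0]
            cs = tree._children[v]
        if not cs:
            return tree._label[v]
        return "(" + ",".join(sorted(canon(c) for c in cs)) + ")"

    return canon(tree.root)


def isomorphic(a: PhyloNetwork, b: PhyloNetwork) -> bool:
    """Exact leaf-labelled isomorphism of two networks (VF2 on the DAGs)."""
    if a.leaves != b.leaves or a.num_edges() != b.num_edges():
        return False
    if len(a._children) != len(b._children):
        return False
    ga = _to_nx(a)
    gb = _to_nx(b)
    nm = isomorphism.categorical_node_match("label", None)
    return isomorphism.DiGraphMatcher(ga, gb, node_match=nm).is_isomorphic()


def _to_nx(net: PhyloNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for v in net.nodes():
        g.add_node(v, label=net.label_of(v))
    g.add_edges_from(net.edges())
    return g


# ------------------------------------------------------------ display oracle
def _displayed_tree(net: PhyloNetwork, keep: Dict[int, int]) -> PhyloTree:
    """Displayed tree for one switching: each reticulation keeps parent keep[v]."""
    kept_children: Dict[int, List[int]] = {}
    for v in net.nodes():
        kept_children[v] = [
            c
            for c in net.children(v)
            if not net.is_reticulation(c) or keep[c] == v
        ]
    # drop dead-end internal nodes (lost all kept children)
    changed = True
    while changed:
        changed = False
        for v, cs in kept_children.items():
            live = [c for c in cs if net.is_leaf(c) or kept_children[c]]
            if len(live) != len(cs):
                kept_children[v] = live
                changed = True

    tree = PhyloTree()
    tree.synthetic_lengths = net.synthetic_lengths

    def build(v: int, acc_len: float, parent_new: int) -> None:
        # walk down unary chains accumulating length
        while True:
            cs = kept_children[v]
            if net.is_leaf(v):
                leaf = tree.new_node()
                tree.add_edge(parent_new, leaf, acc_len)
                tree.set_label(leaf, net.label_of(v))
                return
            if len(cs) == 1:
                acc_len += net.length(v, cs[0])
                v = cs[0]
                continue
            node = tree.new_node()
            tree.add_edge(parent_new, node, acc_len)
            for c in cs:
                build(c, net.length(v, c), node)
            return

    root = tree.new_node()
    tree.root = root
    (top,) = net.children(net.root)
    build(top, net.length(net.root, top), root)
    return tree


def iter_switchings(net: PhyloNetwork) -> Iterator[PhyloTree]:
    """Yield the displayed tree of every per-reticulation parent choice."""
    retics = [v for v in net.nodes() if net.is_reticulation(v)]
    for combo in itertools.product(*(net.parents(v) for v in retics)):
        yield _displayed_tree(net, dict(zip(retics, combo)))


def restrict_tree(tree: PhyloNetwork, taxa: Set[str]) -> PhyloTree:
    """Restriction of a tree to a taxon subset, suppressing unary nodes."""
    out = PhyloTree()
    out.synthetic_lengths = tree.synthetic_lengths

    def build(v: int, acc: float, parent_new: Optional[int]) -> Optional[int]:
        lab = tree.label_of(v)
        if lab is not None:
            if lab not in taxa:
                return None
            leaf = out.new_node()
            out.set_label(leaf, lab)
            if parent_new is not None:
                out.add_edge(parent_new, leaf, acc)
            return leaf
        kept = []
        for c in tree.children(v):
            kept.append((c, tree.length(v, c)))
        # recurse: collect surviving children
        survivors = []
        for c, l in kept:
            r = _probe(c)
            if r:
                survivors.append((c, l))
        if not survivors:
            return None
        if len(survivors) == 1:
            c, l = survivors[0]
            return build(c, acc + l, parent_new)
        node = out.new_node()
        if parent_new is not None:
            out.add_edge(parent_new, node, acc)
        for c, l in survivors:
            build(c, l, node)
        return node

    def _probe(v: int) -> bool:
        lab = tree.label_of(v)
        if lab is not None:
            return lab in taxa
        return any(_probe(c) for c in tree.children(v))

    root = out.new_node()
    out.root = root
    (top,) = tree.children(tree.root)
    res = build(top, tree.length(tree.root, top), root)
    if res is None:
        raise ValueError("restriction removed every leaf")
    return out


def displays(net: PhyloNetwork, tree: PhyloNetwork, max_r: int = 14) -> bool:
    """Brute-force display test: is *tree* embedded in *net*?

    Enumerates the 2^r switchings of the network, restricts each displayed
    tree to the leaf set of *tree* and compares canonical forms.  Intended as
    a verification oracle for small r; raises ResourceError beyond *max_r*.
    """
    r = net.reticulation_number()
    if r > max_r:
        raise ResourceError(f"{r} reticulations exceed the enumeration budget")
    taxa = tree.leaves
    if not taxa <= net.leaves:
        return False
    target = tree_canonical(tree)
    seen = set()
    for disp in iter_switchings(net):
        c = tree_canonical(disp)
        if c in seen:
            continue
        seen.add(c)
        if tree_canonical(restrict_tree(disp, taxa)) == target:
            return True
    return False
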