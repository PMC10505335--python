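"""Reading and writing trees, networks and cherry-picking sequences.

Trees are exchanged in Newick (parsed with dendropy); networks are written in
extended Newick (reticulations as ``#H`` tags) and in a plain edge-list format
``parent<TAB>child<TAB>length``; cherry-picking sequences as one
``x<TAB>y`` pair per line.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

from .phylo import DEFAULT_LENGTH, PhyloNetwork, PhyloTree


# ------------------------------------------------------------------- newick
def tree_from_newick(newick: str) -> PhyloTree:
    """Parse a rooted binary tree; missing branch lengths default to 1.0."""
    dt = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree = PhyloTree()
    missing = False

    def convert(dnode, parent_new: int, edge_len: Optional[float]) -> None:
        nonlocal missing
        if edge_len is None:
            missing = True
            edge_len = DEFAULT_LENGTH
        node = tree.new_node()
        tree.add_edge(parent_new, node, edge_len)
        kids = dnode.child_nodes()
        if not kids:
            if dnode.taxon is None:
                raise ValueError("unlabelled leaf in newick input")
            tree.set_label(node, dnode.taxon.label)
            return
        if len(kids) != 2:
            raise ValueError("only binary trees are supported")
        for k in kids:
            convert(k, node, k.edge.length)

    root = tree.new_node()
    tree.root = root
    seed = dt.seed_node
    kids = seed.child_nodes()
    if len(kids) == 1:
        # already has a unary root edge
        convert(kids[0], root, kids[0].edge.length)
    else:
        convert(seed, root, seed.edge.length)
    tree.synthetic_lengths = missing
    tree.validate()
    return tree


def tree_to_newick(tree: PhyloTree, lengths: bool = True) -> str:
    def fmt(v: int) -> str:
        lab = tree.label_of(v)
        if lab is not None:
            return lab
        return "(" + ",".join(
            fmt(c) + (f":{tree.length(v, c):g}" if lengths else "")
            for c in tree.children(v)
        ) + ")"

    (top,) = tree.children(tree.root)
    s = fmt(top)
    if lengths:
        s += f":{tree.length(tree.root, top):g}"
    return s + ";"


def trees_from_newick_file(path: str) -> List[PhyloTree]:
    """One newick tree per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(tree_from_newick(line))
    return trees


def trees_to_newick_file(trees: Sequence[PhyloTree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(tree_to_newick(t) + "\n")


# ----------------------------------------------------------- extended newick
def network_to_enewick(net: PhyloNetwork, lengths: bool = True) -> str:
    """Extended Newick: each reticulation printed once in full, then as #Hi."""
    tags: Dict[int, str] = {}
    seen: set = set()
    i = 0
    for v in net.nodes():
        if net.is_reticulation(v):
            i += 1
            tags[v] = f"#H{i}"

    def fmt(v: int) -> str:
        if v in tags:
            if v in seen:
                return tags[v]
            seen.add(v)
            inner = _body(v)
            return inner + tags[v]
        return _body(v)

    def _body(v: int) -> str:
        lab = net.label_of(v)
        if lab is not None:
            return lab
        parts = []
        for c in net.children(v):
            s = fmt(c)
            if lengths:
                s += f":{net.length(v, c):g}"
            parts.append(s)
        return "(" + ",".join(parts) + ")" if parts else ""

    (top,) = net.children(net.root)
    s = fmt(top)
    if lengths:
        s += f":{net.length(net.root, top):g}"
    return s + ";"


# ------------------------------------------------------------------ edgelist
def network_to_edgelist(net: PhyloNetwork, path: str) -> None:
    """Write ``parent<TAB>child<TAB>length`` rows; leaves named by taxon."""

    def name(v: int) -> str:
        lab = net.label_of(v)
        return lab if lab is not None else f"_{v}"

    with open(path, "w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{name(u)}\t{name(v)}\t{net.length(u, v):g}\n")


def network_from_edgelist(path: str) -> PhyloNetwork:
    net = PhyloNetwork()
    ids: Dict[str, int] = {}

    def node(name: str) -> int:
        if name not in ids:
            ids[name] = net.new_node()
            if not name.startswith("_"):
                net.set_label(ids[name], name)
        return ids[name]

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v, l = line.split("\t")
            net.add_edge(node(u), node(v), float(l))
    roots = [v for v in net.nodes() if net.in_degree(v) == 0]
    if len(roots) != 1:
        raise ValueError("edge list does not describe a single-rooted network")
    net.root = roots[0]
    return net


# ----------------------------------------------------------------- sequences
def cps_to_file(pairs: Sequence[Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for x, y in pairs:
            fh.write(f"{x}\t{y}\n")


def cps_from_file(path: str) -> List[Tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                x, y = line.split("\t")
                pairs.append((x, y))
    return pairs
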