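"""Synthetic network generators and displayed-tree extraction.

Three stochastic growers of rooted binary networks with branch lengths:

* ``generate_lgt`` — a lateral-gene-transfer growth process: pendant
  lineages speciate (probability 1 - alpha per step) or receive a horizontal
  transfer arc from a coexisting lineage (probability alpha, accepted with
  probability beta), producing orchard networks.  Waiting times between
  events are exponential, so branch lengths follow a coalescent-like clock;
  transfer arcs are horizontal (length 0).
* ``generate_normal`` — the same process, but a transfer is only accepted if
  the network stays normal (tree-child with incomparable reticulation
  parents).  A normal network is an optimal network for the set of its
  exhaustive displayed trees, which makes these instances reference-valued.
* ``generate_zods`` — a birth-hybridization process with speciation rate
  lambda and hybridization rate nu per lineage pair; hybridizations are
  unconstrained, so the output may be non-orchard.

``exhaustive_trees`` enumerates the <= 2^r distinct displayed trees on the
full taxon set; ``sample_displayed_trees`` draws a random subset of them
without full enumeration.  ``remove_leaves`` drops a percentage of leaves per
tree, emulating inputs with differing leaf sets.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .phylo import (
    PhyloNetwork,
    PhyloTree,
    ResourceError,
    iter_switchings,
    restrict_tree,
    tree_canonical,
)


@dataclass
class GenConfig:
    """Parameters of one simulated instance family."""

    generator: str = "lgt"  # lgt | normal | zods
    leaves: int = 20
    reticulations: int = 5
    alpha: Optional[float] = None  # LGT event probability; sampled U[0.1,0.5] if None
    beta: float = 1.0  # acceptance probability of a transfer event
    lam: float = 1.0  # ZODS speciation rate
    nu: Optional[float] = None  # ZODS hybridization rate; sampled U[1e-4,0.4] if None
    n_trees: Optional[int] = None  # trees to extract (None = all exhaustive)
    drop_leaves_pct: float = 0.0
    seed: int = 0

    def as_dict(self) -> Dict:
        return dict(self.__dict__)


# ----------------------------------------------------------------- growth
class _Grower:
    """Shared machinery: a set of open pendant lineages growing in time."""

    def __init__(self, rng: random.Random) -> None:
        self.rng = rng
        self.net = PhyloNetwork()
        root = self.net.new_node()
        self.net.root = root
        first = self.net.new_node()
        self.net.add_edge(root, first, 0.0)
        # open lineages: pendant nodes whose edge grows with time
        self.open: List[int] = [first]
        self.birth: Dict[int, float] = {root: 0.0, first: 0.0}
        self.time = 0.0

    def _extend(self, node: int, now: float) -> None:
        (p,) = self.net.parents(node)
        self.net._length[(p, node)] += now - self.birth[node]
        self.birth[node] = now

    def speciate(self, node: int, now: float) -> None:
        self._extend(node, now)
        a = self.net.new_node()
        b = self.net.new_node()
        self.net.add_edge(node, a, 0.0)
        self.net.add_edge(node, b, 0.0)
        self.birth[a] = self.birth[b] = now
        self.open.remove(node)
        self.open.extend([a, b])

    def transfer(self, donor: int, recipient: int, now: float) -> Tuple[int, int]:
        """Horizontal arc donor -> recipient; recipient becomes a reticulation.

        The donor node becomes a tree node with a continuing lineage and the
        horizontal arc (length 0); the recipient becomes a reticulation whose
        single child continues the recipient lineage.
        """
        self._extend(donor, now)
        self._extend(recipient, now)
        d2 = self.net.new_node()
        r2 = self.net.new_node()
        self.net.add_edge(donor, d2, 0.0)
        self.net.add_edge(recipient, r2, 0.0)
        self.net.add_edge(donor, recipient, 0.0)  # the horizontal arc
        self.birth[d2] = self.birth[r2] = now
        self.open.remove(donor)
        self.open.remove(recipient)
        self.open.extend([d2, r2])
        return d2, r2

    def hybridize(self, u: int, v: int, now: float) -> bool:
        """Merge the open lineages u and v into a single hybrid lineage.

        The two pendant edges are redirected into one new reticulation node
        with in-edges of positive length; such merges are unconstrained and
        can make the network non-orchard.  Lineage count decreases by one.
        Sibling lineages are skipped (a merge would create parallel edges).
        """
        (pu,) = self.net.parents(u)
        (pv,) = self.net.parents(v)
        if pu == pv:
            return False
        self._extend(u, now)
        self._extend(v, now)
        lu = self.net._length[(pu, u)]
        lv = self.net._length[(pv, v)]
        self.net.remove_node(u)
        self.net.remove_node(v)
        del self.birth[u]
        del self.birth[v]
        h = self.net.new_node()
        self.net.add_edge(pu, h, lu)
        self.net.add_edge(pv, h, lv)
        h2 = self.net.new_node()
        self.net.add_edge(h, h2, 0.0)
        self.birth[h2] = now
        self.open.remove(u)
        self.open.remove(v)
        self.open.append(h2)
        return True

    def finish(self, extra: float) -> PhyloNetwork:
        now = self.time + extra
        for i, node in enumerate(self.open):
            self._extend(node, now)
            self.net.set_label(node, f"t{i + 1}")
        if len(self.open) == 1:
            raise ValueError("cannot finish with a single lineage")
        return self.net


def _is_tree_child(net: PhyloNetwork) -> bool:
    """Every non-leaf node has at least one tree-node or leaf child."""
    for v in net.nodes():
        cs = net.children(v)
        if cs and all(net.is_reticulation(c) for c in cs):
            return False
    return True


def _ancestors(net: PhyloNetwork, v: int) -> Set[int]:
    out: Set[int] = set()
    stack = [v]
    while stack:
        u = stack.pop()
        for p in net.parents(u):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def is_normal(net: PhyloNetwork) -> bool:
    """Tree-child and no reticulation has comparable parents."""
    if not _is_tree_child(net):
        return False
    for v in net.nodes():
        if net.is_reticulation(v):
            a, b = net.parents(v)
            if a in _ancestors(net, b) or b in _ancestors(net, a):
                return False
    return True


def is_orchard(net: PhyloNetwork) -> bool:
    """Constructive check: fully reducible by repeated reducible-pair picks."""
    from .phylo import reducible_pairs

    work = net.copy()
    while not work.is_fully_reduced():
        pairs = reducible_pairs(work)
        if not pairs:
            return False
        work.reduce_pair(pairs[0])
    return True


def _grow(
    leaves: int,
    reticulations: int,
    alpha: float,
    beta: float,
    rng: random.Random,
    normal: bool,
    max_steps: int = 10000,
) -> Optional[PhyloNetwork]:
    g = _Grower(rng)
    rets = 0
    for _ in range(max_steps):
        k = len(g.open)
        if k >= leaves and rets >= reticulations:
            break
        g.time += rng.expovariate(max(k, 1))
        do_transfer = (
            k >= 2
            and rets < reticulations
            and (k >= leaves or rng.random() < alpha)
            and rng.random() < beta
        )
        if do_transfer:
            donor, recipient = rng.sample(g.open, 2)
            d2, r2 = g.transfer(donor, recipient, g.time)
            if normal and not is_normal(g.net):
                _undo_transfer(g, donor, recipient, d2, r2)
                continue
            rets += 1
        elif k < leaves:
            g.speciate(g.open[rng.randrange(k)], g.time)
        else:
            continue
    else:
        return None
    if len(g.open) != leaves or rets != reticulations:
        return None
    net = g.finish(rng.expovariate(1.0))
    return net


def _undo_transfer(
    g: _Grower, donor: int, recipient: int, d2: int, r2: int
) -> None:
    """Revert a transfer(): remove the two new nodes and the horizontal arc."""
    g.net.remove_node(d2)
    g.net.remove_node(r2)
    g.net.remove_edge(donor, recipient)
    del g.birth[d2]
    del g.birth[r2]
    g.open.remove(d2)
    g.open.remove(r2)
    g.open.extend([donor, recipient])


def _strip_redundant_reticulations(
    net: PhyloNetwork, max_enum_r: int = 8
) -> PhyloNetwork:
    """Remove reticulation edges whose deletion keeps the exhaustive tree set.

    Exact (full 2^r enumeration) up to *max_enum_r* reticulations; larger
    networks are returned unchanged.
    """
    work = net
    while True:
        r = work.reticulation_number()
        if r == 0 or r > max_enum_r:
            return work
        base = _canon_set(work)
        removed = False
        for v in list(work.nodes()):
            if v not in work._children or not work.is_reticulation(v):
                continue
            for p in list(work.parents(v)):
                cand = work.copy()
                cand.remove_edge(p, v)
                cand._suppress(v)
                if cand.out_degree(p) == 1 and cand.in_degree(p) == 1:
                    cand._suppress(p)
                try:
                    cand.validate()
                except ValueError:
                    continue
                if _canon_set(cand) == base:
                    work = cand
                    removed = True
                    break
            if removed:
                break
        if not removed:
            return work


def _canon_set(net: PhyloNetwork) -> Set[str]:
    return {tree_canonical(t) for t in iter_switchings(net)}


# -------------------------------------------------------------- public API
def generate_lgt(
    leaves: int,
    reticulations: int,
    alpha: Optional[float] = None,
    beta: float = 1.0,
    seed: int = 0,
    max_tries: int = 50,
    strip_redundant: bool = True,
) -> PhyloNetwork:
    """Grow a binary orchard network by speciation and lateral transfer."""
    rng = random.Random(seed)
    for _ in range(max_tries):
        a = alpha if alpha is not None else rng.uniform(0.1, 0.5)
        net = _grow(leaves, reticulations, a, beta, rng, normal=False)
        if net is None:
            continue
        if strip_redundant:
            net = _strip_redundant_reticulations(net)
            if net.reticulation_number() != reticulations:
                continue
        net.validate()
        return net
    raise ResourceError(
        f"could not reach {leaves} leaves / {reticulations} reticulations"
    )


def generate_normal(
    leaves: int,
    reticulations: int,
    alpha: Optional[float] = None,
    beta: float = 1.0,
    seed: int = 0,
    max_tries: int = 200,
) -> PhyloNetwork:
    """Grow a normal network (tree-child, incomparable reticulation parents)."""
    rng = random.Random(seed)
    for _ in range(max_tries):
        a = alpha if alpha is not None else rng.uniform(0.1, 0.5)
        net = _grow(leaves, reticulations, a, beta, rng, normal=True)
        if net is None:
            continue
        net.validate()
        if not is_normal(net):  # defensive; the growth loop already checks
            continue
        return net
    raise ResourceError(
        f"could not grow a normal network with {leaves} leaves / "
        f"{reticulations} reticulations"
    )


def generate_zods(
    leaves: int,
    lam: float = 1.0,
    nu: Optional[float] = None,
    seed: int = 0,
    max_rets: Optional[int] = None,
    max_steps: int = 10000,
    max_tries: int = 50,
) -> PhyloNetwork:
    """Birth-hybridization growth; output may be non-orchard.

    Lineages speciate at rate lam each and pairs of lineages merge into a
    hybrid at rate nu per pair; the walk stops at *leaves* lineages.  High nu
    runs can stall (merges shrink the lineage count), in which case the
    growth is restarted; *max_rets*, when given, rejects networks with more
    reticulations (the instance-selection knob of grouped experiments).
    """
    rng = random.Random(seed)
    for _ in range(max_tries):
        nu_i = nu if nu is not None else rng.uniform(0.0001, 0.4)
        g = _Grower(rng)
        for _ in range(max_steps):
            k = len(g.open)
            if k >= leaves:
                break
            rate_spec = lam * k
            rate_hyb = nu_i * k * (k - 1) / 2.0
            total = rate_spec + rate_hyb
            g.time += rng.expovariate(total)
            if k < 2 or rng.random() < rate_spec / total:
                g.speciate(g.open[rng.randrange(k)], g.time)
            else:
                u, v = rng.sample(g.open, 2)
                g.hybridize(u, v, g.time)  # no-op for sibling lineages
        else:
            continue
        net = g.finish(rng.expovariate(1.0))
        if max_rets is not None and net.reticulation_number() > max_rets:
            continue
        net.validate()
        return net
    raise ResourceError("ZODS growth did not reach the leaf target")


def exhaustive_trees(net: PhyloNetwork, max_r: int = 10) -> List[PhyloTree]:
    """All distinct displayed trees on the full taxon set (<= 2^r of them)."""
    if net.reticulation_number() > max_r:
        raise ResourceError("too many reticulations for exhaustive enumeration")
    seen: Set[str] = set()
    out: List[PhyloTree] = []
    for t in iter_switchings(net):
        c = tree_canonical(t)
        if c not in seen:
            seen.add(c)
            out.append(t)
    return out


def sample_displayed_trees(
    net: PhyloNetwork, count: int, seed: int = 0, max_tries_factor: int = 50
) -> List[PhyloTree]:
    """Random distinct exhaustive displayed trees via random switchings."""
    from .phylo import _displayed_tree

    rng = random.Random(seed)
    retics = [v for v in net.nodes() if net.is_reticulation(v)]
    if len(retics) <= 10 and 2 ** len(retics) <= max(2 * count, 16):
        all_trees = exhaustive_trees(net)
        if count >= len(all_trees):
            return all_trees
        return [all_trees[i] for i in sorted(rng.sample(range(len(all_trees)), count))]
    seen: Set[str] = set()
    out: List[PhyloTree] = []
    for _ in range(max_tries_factor * count):
        keep = {v: net.parents(v)[rng.randrange(len(net.parents(v)))] for v in retics}
        t = _displayed_tree(net, keep)
        c = tree_canonical(t)
        if c not in seen:
            seen.add(c)
            out.append(t)
            if len(out) == count:
                return out
    return out


def subsample_trees(
    trees: Sequence[PhyloTree], count: int, seed: int = 0
) -> List[PhyloTree]:
    if count > len(trees):
        raise ValueError("cannot subsample more trees than available")
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(trees)), count))
    return [trees[i] for i in idx]


def remove_leaves(
    trees: Sequence[PhyloTree], pct: float, seed: int = 0
) -> List[PhyloTree]:
    """Drop round(pct% of leaves) per tree uniformly at random.

    Trees left with fewer than two leaves are discarded.
    """
    if not 0 <= pct < 100:
        raise ValueError("pct must be in [0, 100)")
    rng = random.Random(seed)
    out: List[PhyloTree] = []
    for t in trees:
        leaves = sorted(t.leaves)
        k = round(pct / 100.0 * len(leaves))
        if k == 0:
            out.append(t.copy())
            continue
        keep = set(leaves) - set(rng.sample(leaves, k))
        if len(keep) < 2:
            continue
        out.append(restrict_tree(t, keep))
    return out


def generate_instance(config: GenConfig) -> Tuple[PhyloNetwork, List[PhyloTree]]:
    """Network plus input tree set for one instance, per the config."""
    if config.generator == "lgt":
        net = generate_lgt(
            config.leaves, config.reticulations, config.alpha, config.beta,
            seed=config.seed,
        )
    elif config.generator == "normal":
        net = generate_normal(
            config.leaves, config.reticulations, config.alpha, config.beta,
            seed=config.seed,
        )
    elif config.generator == "zods":
        net = generate_zods(config.leaves, config.lam, config.nu, seed=config.seed)
    else:
        raise ValueError(f"unknown generator {config.generator!r}")
    if config.n_trees is None:
        trees = exhaustive_trees(net)
    else:
        trees = sample_displayed_trees(net, config.n_trees, seed=config.seed + 1)
    if config.drop_leaves_pct:
        trees = remove_leaves(trees, config.drop_leaves_pct, seed=config.seed + 2)
    return net, trees
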