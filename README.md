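# cphnet

Cherry-picking heuristics for building phylogenetic networks from trees.

Given a set of rooted **binary** phylogenetic trees — gene trees whose leaf
sets may be (different) subsets of a common taxon set — `cphnet` constructs a
single binary **orchard network** that displays every input tree, trying to
keep the number of reticulations (hybridization / lateral-transfer events)
small. Exact solvers for this *hybridization* problem scale poorly with the
number of trees and reticulations; the cherry-picking framework trades
optimality for feasibility guarantees and practical running times.

## The method

An ordered leaf pair (x, y) is a **cherry** if x and y share a parent, and a
**reticulated cherry** if the parent of x is a reticulation fed by the parent
of y. *Picking* a cherry deletes x (merging the freed edges, branch lengths
summed); picking a reticulated cherry deletes the cross edge. A
**cherry-picking sequence** (CPS) S = (x₁,y₁),…,(xₙ,yₙ) satisfies
yᵢ ∈ {xᵢ₊₁,…,xₙ,yₙ}; a network is *orchard* if some CPS reduces it to a
single leaf.

The heuristic loop repeatedly appends a pair that is a cherry in at least one
(partially reduced) input tree and reduces it in all trees, then completes
the sequence. Adding the pairs back in reverse order — a new leaf becomes a
cherry, an existing leaf gets a reticulation — rebuilds the unique binary
orchard network for which S is a minimum-length CPS. That network displays
every tree the sequence fully reduces, and its reticulation number is exactly

    r(N) = |S| − |X| + 1,

so shorter sequences mean better networks. Pickers:

| picker        | rule |
|---------------|------|
| `rand`        | uniform over reducible pairs |
| `lowpair`     | lowest mean height (branch lengths) over trees where reducible |
| `trivialrand` | a random **trivial** pair (reducible wherever both leaves occur) if any, else random; combined with *tree expansion* |
| `ml` / `trivialml` | a random forest, trained on simulated networks, scores each candidate by its predicted probability of being a cherry or reticulated cherry of the unknown good network (19 features; threshold τ controls randomness) |
| `featimp`     | no model: sequential top-α% filter on the most informative features (trivialness, topological leaf distance, LCA-distance ratio, depth ratio) |

*Tree expansion*: before reducing a trivial pair (x, y), trees containing x
but not y have leaf x replaced by the cherry (x, y) — equivalently, x is
relabelled y — which removes x from the whole tree set and provably preserves
displayability of the original trees.

## Worked example

```python
from cphnet import construct_network, displays, tree_from_newick

trees = [tree_from_newick("((w,x),(y,z));"),
         tree_from_newick("(((x,y),w),z);")]
net, seq = construct_network(trees, heuristic="trivialrand", runs=50, seed=1)
print(seq.pairs, net.reticulation_number())
```

prints

```
cherry-picking sequence: [('y', 'z'), ('x', 'y'), ('w', 'y'), ('y', 'z')]
sequence length |S| = 4  taxa |X| = 4
reticulations r = |S| - |X| + 1 = 1
displays every input tree: True
network (extended newick): ((w,(x,(y)#H1)),(z,#H1));
```

(run `python examples/01_combine_trees.py`): the two trees disagree only on
where x attaches, and one hybrid edge explains both — the best possible,
since any network displaying two distinct trees needs r ≥ 1. The other
`examples/` scripts cover reconstruction from a printed sequence, simulation
plus heuristic comparison (`trivialrand` best-of-100 reaches ratio 1.00 to
the generating network on an instance of 5 trees with 20 leaves), training
and running the learned picker, and the tree-expansion ablation.

A thin CLI wraps the same API:

```bash
cph generate --kind lgt --leaves 20 --rets 5 --trees 10 --seed 1 --out inst/
cph run --trees inst/trees.nwk --heuristic trivialrand --runs 200 --seed 1
cph train --networks lgt --n-networks 100 --max-leaves 20 --out model.joblib
```

## Simulators

`cphnet.simgen` grows the study's three network families with branch
lengths: LGT networks (speciation plus horizontal transfer arcs; orchard by
construction, redundant reticulations stripped), normal networks (transfer
accepted only if the network stays tree-child with incomparable reticulation
parents — then the network is *optimal* for its exhaustive displayed trees,
giving certified reference values), and ZODS-style birth-hybridization
networks (unconstrained merges; often non-orchard). `exhaustive_trees`
enumerates the ≤ 2^r displayed trees; `remove_leaves` emulates trees with
missing taxa.

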