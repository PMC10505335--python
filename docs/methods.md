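# Methods

## Model and objects

A phylogenetic network here is a rooted binary DAG: the root has in-degree 0
and out-degree 1, every other node is a tree node (in 1, out 2), a
reticulation (in 2, out 1) or a labelled leaf (in 1, out 0). The
reticulation number is r(N) = Σ_v max(0, d⁻(v) − 1); binary networks carry
|X| + r(N) − 1 tree nodes, an identity the validator enforces after every
operation. Branch lengths are optional; when the input omits them every
edge defaults to 1.0 and the object is flagged `synthetic_lengths`, so the
distance-based features remain defined while the topological variants stay
authoritative. Parallel edges are excluded by construction (suppression
refuses to create one).

A tree is *displayed* in a network if it embeds with edge-disjoint paths
respecting leaf labels. The `displays` oracle enumerates the 2^r
per-reticulation parent choices, restricts each resulting tree to the query
leaf set and compares canonical forms; it is a verification tool for small
r (budget guarded), not a scalable algorithm, and the test suite
cross-checks it against an independent cluster-set formulation.

## The heuristic loop

The loop picks an ordered pair that is currently a cherry in at least one
input tree, appends it and reduces it everywhere, until all trees are single
leaves; the partial sequence is then completed so that every second element
reappears later as a first element. The completion rule chains the
unresolved second elements in sorted order, appending (d₁,d₂),(d₂,d₃),…;
this is linear-time, deterministic, never affects the already-reduced trees
and adds no reticulations to the reconstruction (each appended pair
introduces its first element as a fresh cherry during reverse addition).
Any linear completion meeting the contract is equally valid; sorting is a
determinism convention.

Reconstruction processes the sequence in reverse with the add-pair rule and
assigns no meaningful branch lengths (the output is topological; edge-list
exports carry 1.0 placeholders flagged synthetic). Node identifiers come
from a deterministic counter so repeated runs are identical.

Without tree expansion, every produced sequence fully reduces a fresh copy
of the inputs. With expansion, the sequence is equivalent to one over
relabelled trees; the preserved guarantee — and the one the tests assert —
is that the reconstructed network displays every *original* input tree.

## Pickers

* **Rand** draws uniformly from the ordered reducible pairs; **LowPair**
  minimises the mean pair height over the trees where the pair is reducible
  (height of a cherry: mean pendant lengths), ties broken uniformly.
* **TrivialRand** prefers a uniformly random trivial pair. A pair is
  trivial when it is a cherry in every active tree containing both leaves
  (trees reduced to one leaf no longer count). Expansion is enabled by
  default for every trivial-aware picker and can be switched off (the
  ablation does exactly that).
* **ML / TrivialML** score each candidate by P(class 1) + P(class 2) from a
  4-class random forest (classes: cherry / reticulated cherry / reversed
  reticulated cherry / neither, relative to the reference network). The
  argmax is taken when it reaches τ ∈ [0,1); otherwise a uniform random
  pair. At τ = 0 the picker is deterministic; argmax ties break
  lexicographically to keep that promise.
* **FeatImp** needs no model: candidates are filtered through four features
  in order — trivialness f4 (higher better), topological leaf distance f8t
  (lower better; cherries of the target have distance 0), LCA-distance
  ratio f11d (higher better) and topological depth ratio f12t (lower
  better) — keeping the top ⌈α%⌉ at each stage (α = 20 by default) and
  returning the best scorer of the final stage. The filter directions are a
  documented convention chosen from the features' rationale (identifying
  reticulated cherries); α = 100 degenerates to ranking by the final
  feature alone, which the tests pin down.

## Features and their maintenance

The 19 features of an ordered pair are: cherry-in-tree ratio, new-cherry
count, before/after cherry-count ratio, trivialness ratio, both-leaves
ratio, and seven depth/distance summaries each in branch-length (d) and
topological (t) variants. Depth of a tree means the maximum depth of any of
its cherries; the leaf distance of a cherry is zero. Denominators: f1 and
f5 divide by the number of active trees, f4 by the trees containing both
leaves — the tree set is always read as the current, partially reduced one.
Undefined averages (empty subset) and zero-denominator ratios contribute
0.0 so vectors are total; this convention is deterministic and shared by
training and inference.

Bookkeeping is incremental where it matters: the tree-set state maintains
cherry→trees, leaf→trees and per-tree cherry indexes under reductions and
expansions, and per-tree depth caches are invalidated by version stamps, so
a feature evaluation after any prefix of a run equals a from-scratch
recomputation — the equivalence is asserted after every step of randomized
runs. The asymptotically optimal amortized update of the original design is
not reproduced; at the problem sizes this package targets the lazy scheme
is faster to verify and impossible to desynchronise.

## Training data

For each simulated orchard network, the exhaustive displayed trees form the
tree set; a uniformly random reducible pair *of the network* is repeatedly
picked and reduced in both network and trees, and at every step each
current ordered cherry of the tree set contributes one labelled data point.
Classes are balanced by downsampling, 10% is held out, and the forest uses
scikit-learn defaults. Tree expansion is not applied during label
generation (the reference network, not the tree set, drives the walk).

## Simulators

* **LGT**: pendant lineages speciate (probability 1 − α per event, α
  sampled U[0.1, 0.5] unless fixed) or receive a horizontal transfer arc
  (probability α, accepted with probability β = 1). Waiting times are
  exponential in the lineage count, giving coalescent-like branch lengths;
  transfer arcs are horizontal (length 0). Growth continues until the
  requested leaf and reticulation counts are met (with retries), and
  reticulation edges whose removal provably leaves the exhaustive tree set
  unchanged are stripped (exact enumeration up to r = 8).
* **Normal**: the same process, but a transfer is kept only if the network
  remains tree-child with incomparable reticulation parents. Normal
  networks are optimal for their exhaustive trees, so their r is a
  certified lower bound for any heuristic output on those instances — the
  basis of the ratio-to-reference evaluation.
* **ZODS**: a continuous-time birth-hybridization walk (speciation rate λ
  per lineage, merge rate ν per lineage pair, ν sampled U[0.0001, 0.4]);
  merges join two open lineages at a common hybrid node with positive-length
  in-edges. Merges shrink the lineage count, so high-ν runs can stall and
  are restarted; outputs are frequently non-orchard and carry many
  redundant reticulations, which is the point of that family.

These growers reproduce the *parameter semantics* of the corresponding
published generators, not their exact sampling internals; no verified
quantity here depends on generator bit-compatibility.

## What the synthetic data does and does not show

The generators produce clock-like branch lengths, exchangeable taxa and
reticulations placed uniformly over coexisting lineages. Real gene-tree
sets carry rate heterogeneity, estimation error, and phylogenetic structure
that random growth does not imitate; a learned picker that excels on these
simulations may transfer poorly to data whose generating process differs
(the non-orchard family already shows the degradation pattern). Passing
tests certify the combinatorial guarantees — display feasibility, the
sequence-length identity, lower bounds on normal instances — not field
accuracy on empirical datasets.

## Problem sizes and numerical choices

The package's own experiments run at desk scale, chosen so the whole suite
re-runs in minutes on one core: the expansion ablation uses 20 instances of
five 20-leaf trees (source networks with 10 reticulations, the smallest
reticulation setting of the LGT experiment grid) and best-of-50 runs; the
bulk sequence-identity check covers ≥ 10⁴ runs over instances with at most
12 taxa; classifier accuracy is demonstrated with 100 training networks of
at most 20 leaves and 5 reticulations (holdout accuracy ≈ 0.88, against a
0.25 balanced-chance baseline; the full-scale protocol of 1000 networks
with up to 100 leaves is a straightforward parameter change). Qualitative
claims are asserted as orderings or generous bands (e.g. the trivial-aware
learned picker staying within 1.5× of the certified optimum on small normal
instances) rather than as point estimates.

All randomness flows from explicit integer seeds through `random.Random`
streams (scikit-learn receives derived integer seeds); repeated runs are
bit-identical. Ties in deterministic argmax selections break
lexicographically on the pair. Degenerate inputs: reducing a non-reducible
pair is a no-op; an empty tree set yields an empty sequence; reconstruction
of a malformed sequence (a second element that never reappears) raises
immediately.

## Known limitations

Nonbinary or unrooted input trees are rejected. The display oracle and the
minimum-CPS search are exponential and deliberately budget-guarded (≤ 6
taxa for the oracle). The ZODS stall/restart behaviour biases very high ν
samples toward smaller effective hybridization intensity. FeatImp's filter
directions are conventions validated empirically, not derived.
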