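"""cphnet — cherry-picking heuristics for phylogenetic network construction.

Combine a set of rooted binary phylogenetic trees into a single binary
orchard network that displays all of them, aiming for a small reticulation
number (the hybridization objective).  The framework builds a
cherry-picking sequence over the tree set with pluggable pickers —
randomised (Rand, LowPair, TrivialRand), machine-learned (ML, TrivialML)
and feature-guided (FeatImp) — and reconstructs the network by reverse pair
addition.
"""

from __future__ import annotations

import random
from typing import List, Optional, Sequence, Tuple

from .cps import (
    CherrySeq,
    LowPairPicker,
    Picker,
    RandPicker,
    TreeSetState,
    TrivialRandPicker,
    complete_seq,
    run_best_of,
    run_cph,
    run_heuristic,
)
from .features import FEATURE_NAMES, FeatureIndex, init_features, update_features
from .io import (
    cps_from_file,
    cps_to_file,
    network_from_edgelist,
    network_to_edgelist,
    network_to_enewick,
    tree_from_newick,
    tree_to_newick,
    trees_from_newick_file,
    trees_to_newick_file,
)
from .ml import (
    CherryClassifier,
    FeatImpPicker,
    MLPicker,
    TrivialMLPicker,
    make_training_set,
    train_classifier,
)
from .phylo import (
    PairKind,
    PhyloNetwork,
    PhyloTree,
    classify_pair,
    displays,
    isomorphic,
    reticulation_number,
)
from .reconstruct import expected_reticulations, min_cps_oracle, network_from_cps
from .simgen import (
    GenConfig,
    exhaustive_trees,
    generate_lgt,
    generate_normal,
    generate_zods,
    remove_leaves,
    sample_displayed_trees,
    subsample_trees,
)

__version__ = "0.1.0"

HEURISTICS = ("rand", "lowpair", "trivialrand", "ml", "trivialml", "featimp")


def make_picker(
    name: str,
    seed: int = 0,
    model: Optional[CherryClassifier] = None,
    tau: float = 0.0,
    alpha: float = 20.0,
) -> Picker:
    """Instantiate a picker by heuristic name."""
    rng = random.Random(seed)
    if name == "rand":
        return RandPicker(rng)
    if name == "lowpair":
        return LowPairPicker(rng)
    if name == "trivialrand":
        return TrivialRandPicker(rng)
    if name == "ml":
        if model is None:
            raise ValueError("heuristic 'ml' requires a trained classifier")
        return MLPicker(model, tau=tau, rng=rng)
    if name == "trivialml":
        if model is None:
            raise ValueError("heuristic 'trivialml' requires a trained classifier")
        return TrivialMLPicker(model, tau=tau, rng=rng)
    if name == "featimp":
        return FeatImpPicker(alpha=alpha)
    raise ValueError(f"unknown heuristic {name!r}")


def construct_network(
    trees: Sequence[PhyloTree],
    heuristic: str = "trivialrand",
    runs: int = 1,
    seed: int = 0,
    expansion: Optional[bool] = None,
    model: Optional[CherryClassifier] = None,
    tau: float = 0.0,
    alpha: float = 20.0,
) -> Tuple[PhyloNetwork, CherrySeq]:
    """One-call interface: trees in, (network, cherry-picking sequence) out.

    Runs the chosen heuristic *runs* times (seeded) and reconstructs the
    network of the best sequence found.
    """
    factory = lambda s: make_picker(heuristic, seed=s, model=model, tau=tau, alpha=alpha)
    seq = run_best_of(trees, factory, n_runs=runs, seed=seed, expansion=expansion)
    return network_from_cps(seq), seq
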