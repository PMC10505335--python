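"""Train a cherry classifier and use it to guide the search.

Labels come from simulated LGT networks: while a network is reduced by
random reducible pairs, every current cherry of its displayed-tree set is
scored as cherry / reticulated cherry / reversed reticulated cherry /
non-reducible in the network.  A random forest learns this 4-way signal and
the ML picker follows its predicted reducibility probability.
"""

import random

from cphnet import construct_network
from cphnet.ml import make_training_set, train_classifier
from cphnet.simgen import exhaustive_trees, generate_lgt

rng = random.Random(0)
networks = [
    generate_lgt(rng.randint(5, 15), rng.randint(1, 4), seed=rng.randrange(2**31))
    for _ in range(30)
]
data = make_training_set(networks, seed=0)
clf, report = train_classifier(data, seed=0)
print(f"balanced data points: {len(data)}")
print(f"holdout accuracy: {report['holdout_accuracy']:.3f} (chance = 0.25)")
print("top-5 features:", list(clf.feature_importances().head(5).index))

test_net = generate_lgt(12, 4, seed=99)
trees = exhaustive_trees(test_net)
for heuristic in ("trivialrand", "trivialml", "featimp"):
    kwargs = {"model": clf} if heuristic == "trivialml" else {}
    out, _ = construct_network(trees, heuristic=heuristic, runs=10, seed=3, **kwargs)
    print(f"{heuristic:12s} best-of-10 r = {out.reticulation_number()} "
          f"(reference r = {test_net.reticulation_number()})")
# The learned picker uses the same features as FeatImp, but weights them by
# what the forest found informative rather than by a fixed filter order.
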