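"""Simulate an instance and compare the randomised heuristics.

Grows an LGT network (20 leaves, 6 reticulations), extracts 5 of its
displayed trees and lets each randomised heuristic take its best of 100
seeded runs.  The generating network's reticulation number is the reference
value (an upper-bound estimate of the optimum for LGT instances).
"""

from cphnet import construct_network
from cphnet.simgen import generate_lgt, sample_displayed_trees

net = generate_lgt(leaves=20, reticulations=6, seed=7)
trees = sample_displayed_trees(net, 5, seed=8)
print(f"reference network: {net.num_leaves()} leaves, r = {net.reticulation_number()}")

for heuristic in ("rand", "lowpair", "trivialrand"):
    out, seq = construct_network(trees, heuristic=heuristic, runs=100, seed=1)
    r = out.reticulation_number()
    print(f"{heuristic:12s} best-of-100 r = {r:2d}  (ratio {r / 6:.2f})")
# TrivialRand (with tree expansion) typically lands closest to the
# reference; plain Rand pays for ignoring trivial pairs.
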