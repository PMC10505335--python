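"""Combine two gene trees into a single orchard network.

Builds the classic two-tree example in which the trees disagree about the
placement of taxon x, runs the TrivialRand heuristic and reconstructs the
network from the resulting cherry-picking sequence.
"""

from cphnet import construct_network, displays, tree_from_newick
from cphnet.io import network_to_enewick

trees = [
    tree_from_newick("((w,x),(y,z));"),
    tree_from_newick("(((x,y),w),z);"),
]

net, seq = construct_network(trees, heuristic="trivialrand", runs=50, seed=1)

print("cherry-picking sequence:", seq.pairs)
print("sequence length |S| =", len(seq), " taxa |X| =", len(seq.taxa()))
print("reticulations r = |S| - |X| + 1 =", net.reticulation_number())
print("displays every input tree:", all(displays(net, t) for t in trees))
print("network (extended newick):", network_to_enewick(net, lengths=False))
# One reticulation suffices: the two trees differ only in where x attaches,
# so a single hybrid edge explains both topologies.
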