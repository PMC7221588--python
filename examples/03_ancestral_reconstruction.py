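"""Marginal ML ancestral reconstruction with confidence masking.

Reconstructs every internal node of a simulated family and masks sites whose
best state has posterior probability <= 0.5 (the threshold used when counting
high-confidence replacements).  Accuracy against the generator's recorded
ancestral sequences is printed.
"""

from bdmshift import SimConfig, discretize_gamma, load_model, marginal_ancestral, simulate_alignment

aln, truth = simulate_alignment(SimConfig(seed=11, n_taxa=16, L=450))
anc = marginal_ancestral(aln, truth.tree, load_model("WAG"), discretize_gamma(1.1990, 2))

correct = total = masked = 0
for node_id in anc.node_ids:
    true_seq = truth.node_sequences[node_id]
    est = anc.sequence(node_id)
    correct += sum(a == b for a, b in zip(est, true_seq))
    masked += anc.masked_sequence(node_id, 0.5).count("x")
    total += len(true_seq)

print(f"{len(anc.node_ids)} internal nodes x {aln.L} sites reconstructed")
print(f"MAP-state accuracy vs simulation truth: {100 * correct / total:.1f}%")
print(f"sites masked at the 0.5 confidence threshold: {masked} "
      f"({100 * masked / total:.1f}%)")
root = truth.tree.root.index
print(f"root reconstruction, first 60 sites (x = low confidence):")
print("  " + anc.masked_sequence(root, 0.5)[:60])
print()
print("High accuracy is expected in this benign regime (moderate branch")
print("lengths, hundreds of sites); masked sites concentrate near the root")
print("and on long branches where the signal decays.")
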