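"""Simulate a protein family with a radical shift on one branch and detect it.

Evolves 16 sequences of 450 residues under WAG+Gamma along a balanced tree
whose central internal branch is long (0.5 subs/site) and carries a radical
tilt (beta = 10): replacements on that branch are reweighted toward
high-BDM exchanges.  The pipeline then reconstructs ancestors by marginal ML
and runs the focal-vs-neighbors contrast.
"""

from bdmshift import (
    SimConfig,
    bdm_branch_test,
    central_internal_branch,
    discretize_gamma,
    load_model,
    marginal_ancestral,
    simulate_alignment,
)

tree = SimConfig(seed=7).resolve_tree()
parent, child = central_internal_branch(tree)
cfg = SimConfig(seed=7, shift_branch=(parent.index, child.index), beta=10.0)
aln, truth = simulate_alignment(cfg)
print(f"simulated {aln.N} sequences x {aln.L} sites; "
      f"shifted branch {parent.index}-{child.index}")

model = load_model("WAG")
rates = discretize_gamma(1.1990, 2)
anc = marginal_ancestral(aln, truth.tree, model, rates)
result = bdm_branch_test(anc, aln, truth.tree, truth.tree.branch(parent.index, child.index))

print(f"focal:     BDM1={result.BDM1:.0f}  R1={result.R1}  "
      f"(BDM/R = {result.BDM1 / result.R1:.1f})")
print(f"neighbors: BDM2={result.BDM2:.0f}  R2={result.R2}  "
      f"(BDM/R = {result.BDM2 / result.R2:.1f})")
print(f"one-tail Fisher P = {result.p_value:.4f}")
print()
print("The shifted branch's replacements are more radical per event than its")
print("neighbors', and the one-tail P reflects that enrichment.")
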