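"""One-tail Fisher exact test on the three published focal-branch tables.

Each table contrasts the summed replacement-difference score (BDM) and the
replacement count (R) on a focal internal branch against its pooled
neighboring branches.  A small P means replacements on the focal branch were
disproportionately radical — evidence of functional shift.
"""

from bdmshift import fisher_one_tail

cases = {
    "RPE65 stem (retinoid isomerase emerged here)": [[1714, 130], [719, 79]],
    "BCOL stem (secreted subfamily)": [[719, 54], [453, 41]],
    "ACOL stem (cytosolic subfamily)": [[1656, 126], [1483, 112]],
}

for label, ((bdm1, r1), (bdm2, r2)) in cases.items():
    p = fisher_one_tail([[bdm1, r1], [bdm2, r2]])
    print(f"{label}")
    print(f"  focal:     BDM1={bdm1:5d}  R1={r1:4d}  (BDM/R = {bdm1 / r1:.1f})")
    print(f"  neighbors: BDM2={bdm2:5d}  R2={r2:4d}  (BDM/R = {bdm2 / r2:.1f})")
    print(f"  one-tail Fisher P = {p:.4f}  (rounds to {p:.2f})")
    print()

print("Only the RPE65 stem shows significantly radical change (P = 0.01),")
print("matching its known dramatic functional divergence; the BCOL and ACOL")
print("stems do not (P = 0.22 and 0.55).")
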