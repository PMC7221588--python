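# bdmshift

Branch functional-shift testing for protein families.

When a protein subfamily emerges on a long internal branch of a phylogeny, a
natural question is whether the amino-acid replacements on that branch were
unusually *radical* — suggestive of a change in function — or just numerous.
`bdmshift` answers this with a BLOSUM62-derived contrast originally applied
to the carotenoid cleavage oxygenase (CCO) superfamily, where the retinoid
isomerase RPE65 arose by dramatic functional change but the secreted BCOL
and cytosolic ACOL subfamilies did not.

The package is aimed at molecular evolution researchers who have a protein
alignment and a tree and want a lightweight, fully inspectable test of
branch-specific functional shift, together with the supporting machinery:
maximum-likelihood ancestral reconstruction, empirical substitution models,
neighbor joining, bootstrap support, and motif scanning to delineate
subfamilies (e.g. presence of the PDPCK palmitoylation motif).

## The test

1. Fit branch lengths on a fixed topology under WAG or JTT with discrete-
   Gamma rate variation (Felsenstein pruning; α = 1.1990, 2 categories by
   default).
2. Reconstruct marginal ML ancestral states at every internal node; keep
   per-site states with posterior probability > 0.5.
3. On the focal internal branch, collect sites where both endpoint states
   are confident and differ. Score each replacement a→b by

   BDM(a, b) = s(a,a) + s(b,b) − 2·s(a,b),

   with *s* the BLOSUM62 score, so identity scores 0 and dissimilar
   exchanges score high. Sum to BDM1 over the R1 replacements.
4. Do the same for the 3–4 neighboring internal branches, pooled: BDM2, R2.
5. Compare `[[BDM1, R1], [BDM2, R2]]` by a one-tail Fisher exact test
   (alternative: focal branch enriched in BDM per replacement). Small P ⇒
   replacements on the focal branch were disproportionately radical.

Radical/conservative replacement measures have known caveats (compositional
and mutational confounders; small counts); results are reported with full
per-site evidence and no multiple-testing correction, and should be read as
screening evidence, not proof of selection.

## Worked example

The three published focal-branch tables (`examples/01_fisher_published_tables.py`):

```
RPE65 stem (retinoid isomerase emerged here)
  focal:     BDM1= 1714  R1= 130  (BDM/R = 13.2)
  neighbors: BDM2=  719  R2=  79  (BDM/R = 9.1)
  one-tail Fisher P = 0.0087  (rounds to 0.01)

BCOL stem (secreted subfamily)
  focal:     BDM1=  719  R1=  54  (BDM/R = 13.3)
  neighbors: BDM2=  453  R2=  41  (BDM/R = 11.0)
  one-tail Fisher P = 0.2238  (rounds to 0.22)

ACOL stem (cytosolic subfamily)
  focal:     BDM1= 1656  R1= 126  (BDM/R = 13.1)
  neighbors: BDM2= 1483  R2= 112  (BDM/R = 13.2)
  one-tail Fisher P = 0.5484  (rounds to 0.55)
```

Only the RPE65 stem, where replacements averaged 13.2 BDM units against 9.1
on its neighbors, is significant: the radical-change signature of its known
functional shift. The other `examples/` scripts simulate a shifted family
end to end, reconstruct ancestors, scan motifs, and select a model by BIC.

A thin CLI mirrors the library:

```sh
bdmshift fisher --table 1714,130,719,79
bdmshift test --aln family.fasta --tree family.nwk --focal 374-375
bdmshift run --config analysis.yaml --out results/
```

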