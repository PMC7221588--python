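# Methods

## Model and likelihood

Sequences evolve under a time-reversible empirical amino-acid model: WAG or
JTT exchangeabilities `S` with stationary frequencies `π`, assembled as
`Q_ij = S_ij π_j` (i ≠ j), diagonal set so rows sum to zero, and scaled so
the expected substitution rate at equilibrium is exactly 1 — branch lengths
are therefore in expected substitutions per site. The matrices ship as
plain-text lower-triangle tables (`src/bdmshift/data/*.dat`) in the layout
used by most phylogenetics packages, so they can be diffed against any
published copy. An optional `+F` variant replaces `π` with alignment counts
(0.5 pseudocount per residue).

Among-site rate variation uses Yang's discrete Gamma: `k` equiprobable
categories from Gamma(α, mean 1), each category's rate the conditional mean
of its quantile bin (this preserves an overall mean of exactly 1; a median
variant is available for compatibility with tools that discretize that way).
Defaults α = 1.1990, k = 2 match the setting the CCO analyses were run at.

Transition matrices come from the spectral decomposition of the
π-symmetrized rate matrix (reversibility guarantees a real spectrum);
`P(t) = exp(Qrt)` is clipped at 0 and row-renormalized to absorb
eigendecomposition round-off (relative error ~1e-13).

Alignment likelihoods use Felsenstein pruning with per-node, per-site,
per-category max-rescaling; scale factors are carried in log space, so the
reported log-likelihood is exact (to ~1e-10) regardless of taxon count.
Gap and `X` characters are missing data: all-ones leaf partials. Trees may
be rooted arbitrarily; all likelihoods and posteriors are invariant to root
placement under these reversible models (tested to 1e-8).

## Branch lengths, distances, trees

Branch lengths are optimized coordinate-wise on the fixed topology:
pre-order sweeps in which each branch is optimized by bounded scalar search
([0, 20] subs/site, Brent) against the exact current likelihood, using the
inside partial below the branch and the outside partial above it (updated as
the sweep descends, so each one-dimensional step is exact Gauss–Seidel and
the total lnL never decreases). Sweeps repeat until |ΔlnL| < tol (default
1e-6) or 25 cycles; non-convergence warns and flags rather than raising.
Topology search is deliberately out of scope: the test consumes a given tree
or a neighbor-joining start.

Pairwise ML distances maximize the two-sequence likelihood from a 20×20
pair-count matrix under the same model+Γ; sites with a gap/`X` in either
sequence are dropped per pair (or alignment-wide with `gap_mode="complete"`).
Pairs with no comparable sites get the maximum distance (20) with a warning.

Neighbor joining is the classic Saitou–Nei agglomeration (Studier–Keppler
Q-matrix). Negative intermediate branch lengths are clamped to zero with
the excess moved to the sibling branch, preserving the pair's path length.
Only classic NJ is implemented (no BioNJ variance weighting) — a deliberate
simplification, as the start tree only seeds branch-length optimization.
Bootstrap support resamples alignment columns with replacement, rebuilds the
NJ tree per replicate, and reports the percentage of replicates containing
each internal-edge bipartition of the reference tree.

## Ancestral reconstruction

Marginal (per-node) reconstruction, not joint: the downstream test
thresholds per-site per-node posterior probabilities, which is a marginal
concept. Posteriors come from the standard inside–outside pass; per-category
posteriors are mixed by each category's per-site posterior weight
(empirical Bayes). The reported state is the MAP state; sites with MAP
probability ≤ 0.5 are masked (`x`) when extracting high-confidence ancestral
sequences. The threshold is strict (kept only when probability > 0.5); an
inclusive variant exists because external tools are ambiguous on ties.
Observed leaf residues count as probability 1; leaf gaps are never confident.

## The BDM branch contrast

`BDM(a, b) = s(a,a) + s(b,b) − 2·s(a,b)` over BLOSUM62 is the default
difference measure: zero on the diagonal, symmetric, nonnegative, e.g.
BDM(D, E) = 6 + 5 − 2·2 = 7. The derivation is a package design choice —
published analyses used a matrix distributed separately — so any symmetric
nonnegative 20×20 matrix can be supplied instead, and every report records
which matrix was used. Under the default, mean BDM per replacement on real
CCO branches is ~9–13, matching the magnitude of the published tables.

A site contributes a replacement to a branch iff both endpoint states are
confident (probability > 0.5, or the endpoint is a leaf residue) and differ.
Requiring *both* endpoints confident is a documented choice; the alternative
(one-sided confidence) is not implemented. Neighbor branches are the 2–4
branches sharing an endpoint with the focal branch, excluding leaf-incident
branches (the contrast is defined between internal branches; fewer than 3
neighbors warns). Neighbor BDM/R are summed, never averaged.

The 2×2 table `[[round(BDM1), R1], [round(BDM2), R2]]` (BDM sums rounded:
Fisher's test is defined on integer tables) is tested one-tailed with the
alternative "focal row enriched in the BDM column", i.e. higher BDM per
replacement on the focal branch. The tail is accumulated from exact
log-factorials (lookup table), relative error < 1e-12; an all-zero table
yields P = NA with an explanation, and a zero margin (a point-mass
conditional distribution) yields P = 1. No multiple-testing correction is
applied, mirroring the original single-branch usage; reports repeat the
caveat that radical/conservative measures are confounded by composition and
small counts.

## Model selection

BIC = −2 lnL + p ln(n) with n = alignment columns and p = free parameters
(branch lengths, +1 for the Gamma shape). Branch lengths are re-optimized
per candidate; under `+G` the shape is profiled over a coarse grid
(0.3, 0.6, default α, 2, 5) rather than continuously optimized — BIC
differences between model families are far larger than the residual profile
error, and the grid keeps selection fast and deterministic.

## Motif scanning

PROSITE-style patterns (fixed residues, `[..]` alternatives, `{..}`
exclusions, `x` wildcards, `(n)`/`(n,m)` repeats) compile to regular
expressions and scan ungapped sequences; matches are non-overlapping,
leftmost first. Positions are reported 1-based in both ungapped-residue
coordinates (the field's C111/C112-style numbering) and alignment columns.
Clade summaries check monophyly of each named leaf set against the tree.

## The simulator

`simulate_alignment` draws a root sequence from the model's stationary
frequencies (or takes one), assigns each site a rate category once, and
evolves each branch by the exact transition matrix at its length × rate —
the same model family the inference assumes, so recovery tests are
well-posed. Default conditions emulate the target regime: 16 taxa on a
balanced tree, 450 sites, WAG+Γ(1.1990, 2), background branches 0.1
subs/site and one long (0.5) internal branch of interest, mirroring the long
subfamily stems the test is applied to.

The alternative hypothesis is generated by a tilt: on the designated branch,
transition probabilities from state a are reweighted by
`exp(β · BDM(a,·)/BDM_max)` and renormalized. β = 0 recovers the null model
exactly (BDM(a,a) = 0); increasing β makes realized replacements
stochastically more radical without changing the model elsewhere. The tilt
is a minimal construction that makes the test's alternative true by
definition — it is not a mechanistic model of functional change.

Generation truth (all internal sequences, per-branch replacement lists with
BDM scores, per-site categories) is recorded; replaying the recorded history
reproduces the emitted alignment bit-for-bit, and recovery/power suites
measure against it. `null_calibration` and `power_curve` run the full
pipeline (ancestral reconstruction on the true tree, then the branch
contrast) per replicate; replicate seeds are spawned from a single seed and
shared across β values so power curves are paired.

What the simulator does **not** emulate: indels (alignments are gap-free;
gap handling is tested with post-hoc edited fixtures), compositional
heterogeneity across lineages, site-specific constraint profiles, and
alignment error. Passing recovery tests therefore demonstrates correctness
of the machinery under the assumed model class, not robustness of the test
on real, messier families.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen to keep the
suites quick while leaving sampling noise well below the asserted margins:
brute-force oracles on 4–5 taxa × 2–5 sites; recovery at 16 taxa × 450
sites (ancestral accuracy ≥ 90% asserted, ~95% typical) and L = 2000–5000
for distances and branch lengths; operating characteristics at 200
replicates per β in {0, 3, 10}. Single-replicate internal-branch-length
estimates at L = 2000 carry ~10–15% relative sampling SD (the estimator is
unbiased), so the 15% recovery tolerance is asserted on the mean over
replicates. The Fisher implementation is verified against exact integer
enumeration for every 2×2 table with total ≤ 60.

## Known limitations

- No topology search, codon models, invariant-sites class, or FreeRate.
- Joint (path-wise) ancestral reconstruction is not implemented.
- The default BDM derivation is an informed reconstruction of a
  separately distributed matrix; numeric BDM sums on the same data may
  differ from published ones even though the Fisher P values on published
  tables reproduce exactly.
- The one-tail P inherits every caveat of radical/conservative replacement
  statistics; treat significant results as hypotheses for follow-up.
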