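# Methods

## Problem setting

Given somatic missense mutations in a tumor, gene expression from the
same tissue, and an upstream MHC class I binding filter, the task is to
rank the candidate mutated 9/10-mers by their probability of activating
CD8+ T cells. The package models two axes known to drive that
probability: the *supply* of epitope precursor reaching the ER (gene
expression, proteasomal cleavage, TAP transport) and the *character of
the mutation* itself (how much the substitution changes residue mass,
hydrophobicity, charge and polarity). MHC-binding affinity is
deliberately not a feature: the model operates on peptides that already
passed a binding filter, where affinity no longer separates the classes
well.

## Features

**Residue deltas.** Computed from a packaged residue table
(tab-separated, user-replaceable):

- masses are *average free amino-acid* masses in Daltons (Gly 75.07 …
  Trp 204.23). Only relative differences enter the classifier, so the
  choice between free amino-acid and residue masses is immaterial as
  long as it is consistent; the free-amino-acid scale is packaged.
- hydrophobicity is the Kyte–Doolittle index (−4.5 … +4.5).
- side-chain charge at pH 7.4 uses Henderson–Hasselbalch on the side
  chain only (acids −1/(1+10^(pKa−pH)), bases +1/(1+10^(pH−pKa)); pKa
  D 3.65, E 4.25, C 8.3, Y 10.07, K 10.53, R 12.48, H 6.0). Backbone
  termini are excluded because the comparison is residue-vs-residue at
  the same sequence position; histidine therefore carries a small
  positive partial charge (~0.04) rather than an arbitrary 0 or +1.
- polarity classes are binary: charged + amide + hydroxyl side chains
  (and Tyr) polar, aliphatic/aromatic/thiol (and Gly) nonpolar. The
  borderline residues (G, C, Y) are configurable via the table file.
  The change category is encoded none=0, polar→nonpolar=1,
  nonpolar→polar=2.
- non-canonical symbols (X, U, B, Z) raise an error rather than being
  imputed; a silently imputed property would corrupt the delta features.

All three scalar deltas are absolute values, hence symmetric in
(wt, mut) and zero on identity.

**TAP score.** An additive 9×20 position-specific matrix. 9-mers are
scored as the sum over positions 1–9. Longer precursors are scored as
the C-terminal residue at matrix position 9 plus α × the contribution of
the first 3 N-terminal residues at positions 1–3 (α = 0.2, span 3, both
configurable) — the consensus-matrix convention for N-extended
precursors, reflecting that TAP selectivity concentrates at the C
terminus and the first N-terminal positions.

**Cleavage score.** Each peptide bond gets a linear score (bias + window
weights, window of 2 residues each side; protein termini padded with a
neutral symbol contributing zero) passed through a logistic sigmoid to
give a per-site cut probability. The peptide's score is
P(C-terminal site cut) × Π(1 − P(internal site cut)): the probability
the proteasome produces the C-terminus *and* spares the body. N-terminal
generation is attributed to ERAP trimming and not modeled, consistent
with a "probability of the full peptide" reading; trimming itself is out
of scope.

**Packaged score tables are synthetic.** The published TAP consensus
matrix and cleavage weight sets are not recoverable in a form that could
be verified here, so the packaged tables
(`tap_matrix.synthetic.tsv`, `cleavage_weights.synthetic.tsv`) are
synthetic stand-ins generated once from a frozen seed with the
qualitative structure of the published models: TAP C-terminal weights
proportional to hydrophobicity plus a basic-residue bonus, cleavage P1
weights favoring hydrophobic residues, negative bias so per-site cut
probabilities are modest. Every scoring function accepts a replacement
table with the same columns; the scoring *algebra* (what the tests pin
down) is independent of the constants.

**Expression.** log10(FPKM + 1); pseudocount and missing-gene policy
(error, or impute-zero with a recorded flag) are configurable. The
candidate filter keeps genes with FPKM ≥ 1 (inclusive boundary).

## Enumeration

Protein positions are 1-based (mutation nomenclature); windows are
0-based half-open internally. For a mutation at position p in a protein
of length L, the number of k-windows containing p is
max(0, min(k, p, L−p+1, L−k+1)); the enumeration is tested exhaustively
against brute force for all L ≤ 25. The wild-type residue is checked
against the FASTA sequence and mismatches are hard errors naming the
position. Every window is scored independently; no per-mutation
aggregation is applied (a max-per-window report exists as a convenience,
outside the modeling path).

## Statistical screen

Per feature, a two-sided Mann–Whitney test (location) and a two-sample
Kolmogorov–Smirnov test (any distributional difference), with raw p
values, −log10 p, group means and significance flags at α = 0.05
(Bonferroni flags available but off by default). The KS p value uses the
asymptotic Kolmogorov distribution, which is adequate at the cohort
sizes targeted (~35 vs ~450) but conservative below ~25 per group — the
Mann–Whitney flag is the calibrated one and is what the null-calibration
tests assert two-sidedly. Constant columns are reported as degenerate
and non-significant rather than raising.

Correlation matrices are computed within each label group separately;
Spearman rank correlation by default (robust to the heavy-tailed
expression scale; Pearson by flag), entries with p ≥ 0.005 masked,
all-masked rows dropped from the rendered matrix while the full matrix
is retained.

## Classifier and evaluation

Random forest, defaults 5000 trees and minimum leaf size 10. The
2×2 cost matrix [[0, 0.15], [1, 0]] (rows true class, order negative,
positive) is realized as per-class observation weights
{negative: 0.15, positive: 1.0} — for tree ensembles this weighting is
the expected-cost-minimizing equivalent of the cost matrix. The score is
the weighted fraction of trees voting positive. Tests and the
acceptance runs use 300 trees: forest AUC stabilizes well below that at
n ≈ 500 × 7, and the package treats tree count as a fidelity/runtime
trade the user controls.

Leave-one-out on the positives: negatives are shuffled with the run seed
and split into n_pos disjoint folds whose sizes differ by at most one
(12–13 negatives per fold at 35/450). Fold i tests positive i plus
negative fold i and trains on everything else, so each sample is tested
exactly once and the pooled scores support a single ROC. Disjointness is
required for the pooled ROC to be valid; configurations that resample
negatives across folds would double-count them.

ROC by threshold sweep over the unique scores (predicted positive iff
score ≥ t), AUC by trapezoid rule, which with ties equals the
pair-counting statistic P(s⁺ > s⁻) + ½P(tie) (asserted to 1e−12 in
tests). Operating metrics mirror the screening use-case: the fraction of
negatives kept at the largest threshold retaining ≥ 50% of positives,
the fraction of positives kept at the smallest threshold removing ≥ 50%
of negatives, and the maxima of accuracy and F1 over thresholds. Because
max-accuracy and max-F1 need not occur at the same threshold, F1 at the
max-accuracy threshold is reported alongside max-F1 (under heavy
imbalance the max-accuracy threshold can predict all-negative, making
that F1 zero — visible in the worked example).

## Synthetic cohorts

Defaults emulate a single-cohort screen: 35 positives, 450 negatives.

*Feature level*: continuous features drawn from group-specific Gaussian
copulas. Marginals (natural scale): expression N(1.0, 0.6) log10 units,
TAP N(0, 2), cleavage logit-normal N(−2, 1.5) squashed through a
sigmoid, deltas folded normals (size 40 ± 25 Da, hydrophobicity 3 ± 2,
charge 0.5 ± 0.5); polarity category Categorical(0.5, 0.25, 0.25).
Positives are mean-shifted by +1.0 SD (expression), +1.0 SD (TAP) and
+0.8 SD (cleavage, on the logit scale); the deltas are unshifted but the
positive group couples size↔hydrophobicity (r = 0.5) and cleavage↔TAP
(r = 0.4) while the negative group is independent — so the two groups
differ in means on the supply axis and in correlation structure on the
mutation axis. The shift sizes are a synthetic calibration chosen so the
full pipeline lands in a held-out AUC regime of roughly 0.8–0.9; they
are not estimates from real data.

*Sequence level*: one 31-residue protein per variant with uniform residue
composition, one missense mutation placed so all 9/10-mer windows fit,
one candidate window sampled per mutation (so the cohort size is exact),
log10 FPKM truncated-normal(1.2, 0.5) at 0 — every gene passes the
FPKM ≥ 1 screen, emulating the upstream expression filter. Features are
computed by the real enumeration/featurization pipeline (asserted in
tests by re-running it on the emitted files). Labels are
Bernoulli(σ(β·z + c)) with z the standardized ER-delivery composite,
β = 3 per SD by default, and c solved by Brent's method so the expected
prevalence matches 35/485. Labels therefore depend on the features only
through the composite; with β = 0 the pipeline must and does return
chance-level AUC.

What passing tests on these cohorts does **not** show: robustness to
real HLA-binding motifs, real mutational signatures, batch effects
between experimental protocols, or covariate shift between tissues —
the generators make no attempt to model any of those.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded from
  the run configuration; identical seeds give bit-identical outputs
  (metrics CSVs compare equal as bytes across reruns).
- Sigmoids are evaluated in the numerically stable branch form.
- One-class datasets, empty samples, < 2 positives for LOO, < 3
  observations per group for correlations, non-finite features and
  schema mismatches are hard errors; constant feature columns in the
  screen are flagged, not fatal.
- Ties in the ROC sweep are handled by the threshold convention
  score ≥ t ⇒ positive; all-tied scores give AUC 0.5 and the degenerate
  operating point (all negatives kept at half-positive retention).

## Known limitations

- The packaged TAP/cleavage constants are synthetic (above); absolute
  TAP/cleavage values are not comparable to published scales, only the
  scoring algebra is.
- Expression is taken as a user-supplied per-gene scalar; no
  isoform-level resolution, no cross-tissue normalization.
- Only missense-derived 9/10-mers: no indels, frameshifts, neo-ORFs, or
  MHC class II.
- The classifier reports a vote fraction, not a calibrated probability.
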