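# Methods

## Problem and model

`acpml` frames anticancer-peptide (ACP) recognition as binary
classification of short peptides (5–50 residues) from sequence composition
alone. No structural, positional or evolutionary information is used: the
modelling assumption is that the compositional signature of ACPs — cationic
and aromatic/aliphatic enrichment — carries enough signal for screening.
Two classifiers are trained independently on the same feature matrix and
optionally combined by consensus, which trades coverage (ambiguous calls)
for precision.

## Feature encodings

* **AAC** (20): residue counts divided by peptide length; columns in
  alphabetical residue order `ACDEFGHIKLMNPQRSTVWY`.
* **DPC** (400): overlapping dipeptide counts divided by the L − 1 windows,
  so the block is a composition summing to 1 for L ≥ 2. The alternative
  reading of "all possible dipeptides" as a constant 400 denominator would
  only rescale the block by (L−1)/400; the windows convention is the
  standard one and keeps the composition invariant. A length-1 peptide
  gets an all-zero DPC block rather than an error, so single-residue
  queries still encode.
* **ATC** (5): C, H, N, O, S atom frequencies, per-residue counts taken
  from the free (unpolymerised) amino-acid molecular formulas
  (G = C₂H₅NO₂, C = C₃H₇NO₂S, …). The table ships as a versioned TSV
  resource (`free_amino_acid_v1`) named in `FeatureConfig`, so a
  residue-in-chain variant can be swapped in without code changes.
  Frequencies are count ratios, hence invariant under sequence repetition.
* **PCP** (11): fractions of residues in ten classes — polar (DERKQN),
  hydrophobic (CVLIMFW), charged (DEKHR), aliphatic (ILV), aromatic
  (FHWY), positively charged (HKR), negatively charged (DE), tiny
  (ACDGST), small (EHILKMNPQV), large (FRWY) — plus peptide mass. The
  classes are deliberately overlapping and non-exhaustive. Fractions are
  reported in [0, 1] (not percent); a constant factor the model pipelines
  absorb. Mass = sum of average residue masses + 18.0153 Da water,
  reported raw in Daltons. This column is ~10³ larger than every other
  feature; see the scaling note below.

Column order is frozen (alphabetical residues; row-major dipeptides;
C,H,N,O,S; class order as listed) and recorded in saved models, which
refuse to score a matrix whose columns differ.

## Curation

Three screening rules run in order: (1) reject sequences with
non-standard residues (ambiguity codes B/J/O/U/X/Z, gaps, anything outside
the 20-letter alphabet); (2) remove peptides longer than 50 residues
(length exactly 50 is kept — the rule is strictly greater); (3) reduce
redundancy at a 90% identity cutoff by greedy incremental clustering:
peptides are scanned longest-first (input order breaks ties) and each
joins the first cluster whose representative it matches at ≥ cutoff, else
founds a new cluster. Identity = identical positions in the best global
alignment / shorter length, with the alignment chosen by Needleman–Wunsch
(match +1, mismatch 0, gap −1) and ties resolved toward more matches — a
fully deterministic rule, implemented as a lexicographic (score, matches)
dynamic program. This reproduces the greedy scheme of CD-HIT without its
word-filter heuristics; borderline pairs that CD-HIT's filter skips may
cluster differently here. Exact pairwise alignment is affordable because
peptides are ≤ 50 residues and datasets are a few thousand sequences.
Redundancy reduction is intended for training data only; benchmark sets
should be evaluated uncurated so that results remain comparable. When a
labelled dataset mixes classes, reduce redundancy within each class to
preserve labels.

## Cross-validation and selection

Stratified k = 10 folds (each fold within one sample per class of perfect
stratification), ten independent repeats with fold seed = base seed +
repeat index. Per repeat, every sample is predicted exactly once by a
model trained on the other nine folds and the metrics come from the pooled
confusion counts; repeats are summarised as mean ± SD. Grid search scores
every hyperparameter point this way and selects the highest mean MCC; ties
go to the first point in scan order (ascending C then γ; ascending ntree,
mtry, nsplit). MCC is the selection target because accuracy is misleading
under class imbalance. Degenerate predictions (an empty predicted class)
set MCC = 0 with an explicit flag; a grid where every point is degenerate
raises a diagnostic error instead of silently returning one.

Metric edge cases: sensitivity/specificity are `None` (not NaN) when the
corresponding class is absent; the Welch test returns `None` for groups
smaller than two or jointly zero-variance groups.

## Scaling, imbalance, seeds

Features are standardised (zero mean, unit variance) *inside each training
fold* for the SVM only, via an sklearn Pipeline, so no test-fold statistic
ever leaks into training; the forest consumes raw features. This choice
matters because of the PCP mass column and shifts SVM results relative to
any implementation that trained on unscaled features. No class weighting
is applied by default. Every stochastic step (fold shuffling, forest
bootstrap, generator sampling) takes an explicit seed recorded in the
trained-model archive.

## Synthetic data generator

The generator draws residues i.i.d. from a class-specific distribution:
uniform over the 20 amino acids with the class's five signature residues
(A,F,K,L,W for positives, D,E,G,N,Q for negatives) enriched ×4, and
lengths uniform in 5–35 (positives) or 5–50 (negatives), 200 peptides per
class by default. These defaults mirror the reported compositional and
length differences between real ACPs and non-ACPs; the ×4 factor gives a
strong but imperfect signal (held-out accuracy ~0.95, not 1.0), so the CV
machinery is genuinely exercised. What the generator does **not** emulate:
positional motifs, amphipathic periodicity, dipeptide-level structure
beyond products of single-residue frequencies, realistic length
histograms, or the feature correlations of curated ACP databases. Passing
tests on this generator therefore demonstrate that the pipeline recovers a
known compositional signal without leakage — not that any particular
accuracy will transfer to real data.

## Problem sizes and defaults used in the checks

The automated checks run reduced settings chosen as a deliberate
compute/fidelity trade-off: SVM grid thinned to log₂ step 2 (13 × 11
points), forest grid ntree {50,150,300,450} × mtry {1,3,7} × nsplit
{2,10}, selection by 5-fold single-repeat CV on a 300-peptide training
split, evaluation on the held-out 100, averaged over a handful of seeds.
The permutation-null check permutes labels and verifies cross-validated
accuracy stays at chance (0.45–0.55), which would fail if any fold-level
leakage (e.g. pre-fitted scaling) were introduced.

## Known limitations

* Benchmark figures from curated ACP databases are not reproduced here;
  doing so requires those external datasets and their exact train/test
  composition. Numbers computed on the synthetic generator characterise
  the pipeline only.
* The greedy clustering is O(n²) alignments; fine for peptide datasets,
  not intended for protein-scale redundancy reduction.
* DPC's 400 columns are sparse for short peptides; with n in the hundreds
  the SVM can prefer very small γ, effectively down-weighting DPC.
* Model archives are joblib pickles: portable across machines but tied to
  compatible scikit-learn versions; the format version is checked on load.
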