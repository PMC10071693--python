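# Methods

## Score definition

The IPASS of a sample is the arithmetic mean over the signature genes of
`log_b(TPM + c)`, with log base `b = 2` and pseudocount `c = 1` by default.
The defining description of the score ("average sum of the log-transformed
TPM values") is ambiguous between a mean and a sum; the mean is the only
reading under which a raw threshold of 0.83 is attainable on a 15-gene
log2 scale (a sum would sit 15x higher), and base 2 with pseudocount 1 is
the transcriptomics convention.  Both parameters are configurable and are
recorded inside the calibration artifact so a frozen signature +
calibration file fully determines scoring.

Raw TPM is taken as given: no re-normalisation or batch correction is
applied before scoring.

## Calibration and classification

Normalisation is min-max onto [-1, 1] using the cohort's raw-score
extremes — the simplest transform consistent with a score "between -1 and
1" and with the published threshold pair (normalised -0.25 <-> raw 0.83).
`fit_calibration` stores the extremes and recomputes the raw threshold as
the raw value mapping to the normalised threshold.  Fitting requires at
least two distinct raw scores; constant cohorts raise a degenerate-
calibration error.

New samples scored against a frozen calibration may fall outside the
calibration range; their normalised scores are clipped into [-1, 1] (with
a warning) rather than triggering a re-fit, keeping classification stable
for prospective use.  Classification is inclusive at the threshold:
`norm >= -0.25` is T-cell infiltrated.

The shipped calibration's endpoints (`raw_min = 0.2`, `raw_max = 1.88`)
are surrogates: the true cohort extremes come from controlled-access data,
so endpoints were chosen once to satisfy the published threshold pair
exactly and are documented as such.

## Signature derivation

Pipeline order: merge IHC labels (hot + altered -> inflamed; indeterminate
samples excluded with a logged count) -> restrict to the immune panel ->
stratified train/test split -> random-forest training on log2(TPM+1) ->
top-k genes by Gini importance -> score the full cohort -> fit calibration
on those scores -> classify -> test-set metrics.

Design choices where the published description is open:

- **Forest hyperparameters** are unstated in the original description;
  defaults are 500 trees, sqrt(p) features per split, unlimited depth,
  Gini impurity — the conventional defaults of the classical R random
  forest. All are configurable and recorded in the derivation report.
- **No hyperparameter tuning.** The original work used a tuning framework,
  which may imply internal cross-validation; this implementation trains a
  single forest at fixed settings, since the selection statistic (Gini
  importance) needs no tuned model.
- **Split rounding.** Per-class training counts use largest-remainder
  apportionment of `floor(n * train_fraction)`; an odd cohort therefore
  puts the extra sample in the test set (matching the published 34/35
  split of 69 labelled samples at fraction 0.5).  Remainder ties go to the
  larger class, then alphabetically.
- **Tie-breaking** in the importance ranking is lexicographic by gene
  symbol, for reproducibility.
- **Class imbalance** is handled by stratification only; no resampling or
  class weights are described in the source procedure, so none are used.
- **Calibration cohort.** By default the calibration is fitted on all
  samples supplied at derivation time; a separate (larger) calibration
  matrix may be passed, mirroring calibration on a full cohort that is a
  superset of the IHC-labelled one.

Anti-leakage is a tested invariant: held-out samples never influence
training or the importance ranking (corrupting their expression leaves the
extracted signature bit-identical).

## Statistical utilities

- Fisher's exact test is two-sided by the probability-mass rule (sum of
  hypergeometric probabilities no larger than the observed table's), the R
  convention; a doubling rule would differ.  The implementation is checked
  against full enumeration for all tables with margins <= 8.
- The two-group comparison implements the standard decision flow:
  Shapiro-Wilk normality on each group and a two-sided F-test for variance
  equality, each at alpha = 0.05; any rejection routes to the Wilcoxon
  rank-sum test, otherwise the pooled two-sample t-test.  (The prose this
  follows states the rule with an apparent negation typo — "used when
  normally distributed or equal variances were not observed" — read here
  as the standard flow.)  Note that with three alpha = 0.05 gatekeeper
  tests, Gaussian equal-variance data select the t-test ~86% of the time,
  not 95%.
- Gene clustering against the score uses plain k-means (k-means++
  initialisation, 10 restarts, seeded) on per-gene z-scores of
  log2(TPM+1); the source description "hierarchical K-means" conflates two
  algorithms, and plain k-means is implemented rather than guessing the
  intent.  Per-cluster affinity to the score is the mean Pearson r of the
  member genes' log-expression with the per-sample scores.
- Percentages are presented to the whole percent with round-half-up,
  matching clinical reporting (0.885 -> 89).

## Biomarker rules

- **Neoantigens**: a predicted epitope passes iff mutant IC50 < 500 nM,
  wild-type IC50 > 500 nM, and gene-level TPM > 1, all strict; a mutation
  with any passing epitope counts as exactly one neoantigen regardless of
  how many HLA alleles it binds.  Gene-level (not transcript-level) TPM is
  used.
- **PD-L1**: IHC-positive iff >= 1% of cells show *membranous* staining
  (cytoplasmic-only staining is negative and must be excluded upstream);
  RNA-high iff TPM > 3.  The 3-TPM cut is descriptive, not validated, and
  is exposed as a parameter.
- **Archetypes**: per-sample score of a gene set = mean cohort z-score of
  log2(TPM+1) over the set's genes present in the matrix; assignment is
  the argmax archetype, alphabetical tie-break with an ambiguity flag.
  This follows the cited archetype methodology conceptually
  (cohort-standardised mean expression); exact parity with the external
  scoring script is not claimed, and the 12 gene sets are user-supplied
  inputs.
- **Clonotypes**: per-sample clone count, total reads, and read
  proportions (sum to 1 within 1e-12); empty samples yield zeros with a
  flag.

## Synthetic cohorts

The generator plants class structure in log2(TPM+1) space: per-gene
baselines ~ Normal(3, 1); informative genes shifted by +2.0 (hot) or +1.2
(altered) log2 units; Gaussian noise sd 0.5; TPM = max(2^x - 1, 0).
Defaults mirror the derivation cohort's shape: 70 labelled samples (45
cold / 13 altered / 12 hot, i.e. 25 inflamed), a 766-gene panel inside a
1000-gene matrix, 15 informative genes.  The altered effect is
intermediate between hot and cold because the derivation merges hot and
altered into one inflamed class.  The -1 offset in the back-transform
mirrors the scoring pseudocount, so planted log2 effects translate
directly into score separation.

Not emulated: tumour-type structure, gene-gene correlation, library-size
artefacts, dropout.  Tests passing on these cohorts demonstrate the
pipeline's correctness and recovery behaviour under the model's own
assumptions, not real-data performance.

The planted-signal recovery benchmark runs the full derivation at 70
samples (25 inflamed / 45 cold) with a 1.5 log2-unit effect for both
inflamed classes across 10 seeds, requiring >= 12/15 planted genes
recovered and >= 0.85 held-out accuracy in at least 8 seeds.  Problem
sizes throughout the suite (cohorts of tens of samples, hundreds to a
thousand genes, 10-seed Monte-Carlo loops) were chosen as the smallest
scales at which the tested properties are statistically meaningful.

## Known limitations

- The published gene ranking and cohort calibration are not reproducible
  without the controlled-access cohorts; the packaged default signature is
  a synthetic stand-in and only 14 of the 15 published member genes are
  identifiable from the public description.
- The printed 87% test accuracy is not an integer fraction of the
  35-sample test set; it is treated as a qualitative benchmark only.
- No survival modelling, multiple-testing correction, or upstream
  quantification (FASTQ/BAM handling) is provided.
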