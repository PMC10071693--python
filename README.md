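# ipass

Tools for quantifying T-cell infiltration of paediatric tumours from bulk
RNA-seq: derivation of the **Immune Paediatric Signature Score (IPASS)**
gene signature from IHC-labelled cohorts, single-sample scoring and
classification, and the ancillary immune biomarker rules used alongside it
(neoantigen filtering, PD-L1 IHC/RNA concordance, immune-archetype
assignment, TCR clonotype summaries).  A seeded synthetic-cohort generator
makes every pipeline stage testable without access to patient data.

Intended users: computational immuno-oncologists working with paediatric
(or other low-infiltration) tumour transcriptomes who want a reproducible,
scriptable implementation of signature derivation and scoring.

## The score

Given a TPM expression matrix and a signature *G* of *k* genes (default
*k* = 15), the raw score of sample *s* is the mean log-expression

```
raw(s) = (1/k) * sum_{g in G} log2(TPM_gs + 1)
```

A cohort calibration `(raw_min, raw_max)` maps the raw score linearly onto
[-1, 1]:

```
norm(s) = 2 * (raw(s) - raw_min) / (raw_max - raw_min) - 1
```

Samples with `norm(s) >= -0.25` are called **T-cell infiltrated** (immune
hot/altered); below that they are **cold**.  With the shipped calibration
the threshold corresponds to a raw score of 0.83.

Signature derivation follows the published procedure: pathologist IHC
classes *hot* and *altered* are merged into an *inflamed* group; the matrix
is restricted to an immune gene panel (766 genes in the original design);
samples are split into stratified train/test halves; a 500-tree Gini
random forest is trained on log2(TPM+1); and the *k* genes with the
highest mean decrease in Gini impurity form the signature.  The published
gene ranking itself cannot be reproduced here — the source cohorts are
controlled-access — so the packaged default signature artifact is derived
from a synthetic fixture cohort, and the 14 published member genes
identifiable from the original report are exposed as
`ipass.REPORTED_SIGNATURE_GENES` for scoring real cohorts.

## Worked example

```python
from ipass import DerivationConfig, derive_ipass, simulate_cohort, SimulationConfig
from ipass.evaluation import metrics_table

cohort = simulate_cohort(SimulationConfig(seed=11))   # 70 samples, 1000 genes
report = derive_ipass(cohort.matrix, cohort.annotations, cohort.panel,
                      DerivationConfig(seed=11))
print("recovered planted genes:",
      len(set(report.signature.genes) & set(cohort.informative_genes)), "/ 15")
print("calibration: raw_min=%.3f raw_max=%.3f raw_threshold=%.3f"
      % (report.calibration.raw_min, report.calibration.raw_max,
         report.calibration.raw_threshold))
print(metrics_table(report.test_metrics).to_string(index=False))
```

prints

```
recovered planted genes: 15 / 15
calibration: raw_min=3.207 raw_max=5.596 raw_threshold=4.103
     metric  value  percent
sensitivity    1.0      100
specificity    1.0      100
        ppv    1.0      100
        npv    1.0      100
   accuracy    1.0      100
```

The forest recovers all 15 planted informative genes, and the held-out
test half of the cohort is classified perfectly — expected on synthetic
data, where the planted class effects (+2.0 log2 units in hot, +1.2 in
altered samples) are clean and uncorrelated; real cohorts are far noisier
(the original signature reported 87% test accuracy).  The calibration line
shows the fitted cohort extremes and the raw score at which the normalised
threshold of -0.25 falls.

The same pipeline is available from a shell:

```
ipass simulate --seed 11 --out-prefix cohort
ipass derive --matrix cohort.matrix.tsv --labels cohort.labels.tsv \
             --panel cohort.panel.txt --k 15 --seed 11 --out-prefix derived
ipass score  --matrix cohort.matrix.tsv --signature derived.signature.json \
             --out scores.tsv
```

plus `evaluate`, `archetype` and `neoantigen-filter`; see `ipass --help`.

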