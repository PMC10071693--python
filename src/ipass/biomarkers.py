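"""Ancillary immune biomarker rules.

- Neoantigen filtering of epitope-prediction tables: keep predicted
  epitopes with mutant IC50 < 500 nM, wild-type IC50 > 500 nM and gene
  expression TPM > 1 (all strict); a mutation with any passing epitope
  counts as exactly one neoantigen, however many HLA alleles it binds.
- PD-L1: IHC-positive iff >= 1% of cells show membranous staining
  (cytoplasmic-only staining does not count and must be excluded from the
  input percentage); RNA-high iff TPM > 3 (a descriptive cut-off, exposed
  as a parameter).
- Immune archetypes: per-sample gene-set scores (mean cohort z-score of
  log2(TPM+1) over the set's genes present in the matrix); each sample is
  assigned the argmax archetype, alphabetical tie-break with a flag.
- TCR clonotype summaries: clone counts, total reads and clone proportions
  per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix
from .errors import FormatError, IpassError, ValidationError

EPITOPE_COLUMNS = ("mutation_id", "hla_allele", "mut_ic50", "wt_ic50", "gene_tpm")


def validate_epitope_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EPITOPE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"epitope table lacks column(s): {missing}")
    for col in ("mut_ic50", "wt_ic50"):
        v = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v) & (v > 0)):
            raise FormatError(f"{col} must be positive and finite")
    tpm = table["gene_tpm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(tpm) & (tpm >= 0)):
        raise FormatError("gene_tpm must be non-negative and finite")
    return table


def filter_neoepitopes(
    table: pd.DataFrame,
    mut_cut: float = 500.0,
    wt_cut: float = 500.0,
    tpm_cut: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Apply the neoantigen rule; returns (passing rows, neoantigen count).

    All three cut-offs are strict inequalities.  The count collapses
    epitopes to mutations: distinct ``mutation_id`` values among passing
    rows.
    """
    if len(table) == 0:
        return table.copy(), 0
    table = validate_epitope_table(table)
    keep = (
        (table["mut_ic50"] < mut_cut)
        & (table["wt_ic50"] > wt_cut)
        & (table["gene_tpm"] > tpm_cut)
    )
    passing = table.loc[keep].copy()
    return passing, int(passing["mutation_id"].nunique())


def classify_pdl1_ihc(percent_positive: float, cut: float = 1.0) -> str:
    """PD-L1 IHC status from the percentage of membranous-staining cells."""
    if not 0 <= percent_positive <= 100:
        raise ValidationError(f"percent must be in [0, 100], got {percent_positive!r}")
    return "positive" if percent_positive >= cut else "negative"


def pdl1_concordance(pairs, tpm_cut: float = 3.0) -> pd.DataFrame:
    """Cross-tabulate IHC status (>=1% membranous) against RNA status
    (TPM > tpm_cut, strict).  Returns a 2x2 DataFrame, IHC rows x RNA cols."""
    out = pd.DataFrame(
        0,
        index=pd.Index(["ihc_positive", "ihc_negative"], name="ihc"),
        columns=pd.Index(["rna_high", "rna_low"], name="rna"),
    )
    for percent, tpm in pairs:
        ihc = "ihc_" + classify_pdl1_ihc(percent)
        rna = "rna_high" if tpm > tpm_cut else "rna_low"
        out.loc[ihc, rna] += 1
    return out


@dataclass(frozen=True)
class ArchetypeSignatureSet:
    """Named immune-archetype gene sets with a scoring-method tag.

    The original archetype work defines 12 sets; any number is accepted
    here since the set definitions are user-supplied inputs.
    """

    sets: dict[str, tuple[str, ...]]
    method: str = "mean_zscore"

    def __post_init__(self):
        if not self.sets:
            raise ValidationError("archetype set collection is empty")
        clean = {}
        for name, genes in self.sets.items():
            genes = tuple(genes)
            if not genes:
                raise ValidationError(f"archetype {name!r} has an empty gene list")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)


def score_archetypes(
    matrix: ExpressionMatrix, sets: ArchetypeSignatureSet
) -> pd.DataFrame:
    """Per-sample, per-archetype scores (samples x archetypes).

    Score = mean over the set's present genes of the per-gene cohort
    z-score of log2(TPM+1).  Needs >= 2 samples (cohort standardisation)
    and at least one gene of every set present with non-zero variance.
    """
    if len(matrix.sample_ids) < 2:
        raise IpassError("archetype scoring needs >= 2 samples for standardisation")
    logx = np.log2(matrix.values + 1.0)
    sd = logx.std(axis=1, ddof=0)
    mean = logx.mean(axis=1)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    scores = {}
    for name, genes in sorted(sets.sets.items()):
        rows = [index[g] for g in genes if g in index and sd[index[g]] > 0]
        if not rows:
            raise IpassError(
                f"archetype {name!r}: no informative genes present in the matrix"
            )
        z = (logx[rows] - mean[rows, None]) / sd[rows, None]
        scores[name] = z.mean(axis=0)
    return pd.DataFrame(scores, index=matrix.sample_ids)


def assign_archetype(scores: pd.DataFrame) -> pd.DataFrame:
    """Argmax archetype per sample; exact ties go to the alphabetically
    first archetype and are flagged."""
    cols = sorted(scores.columns)
    ordered = scores[cols]
    rows = []
    for sample, row in ordered.iterrows():
        best = row.max()
        winners = [c for c in cols if row[c] == best]
        rows.append(
            {"sample_id": sample, "archetype": winners[0], "tied": len(winners) > 1}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def summarize_clones(table: dict[str, list[tuple[str, int]]]) -> pd.DataFrame:
    """Per-sample clonotype summary: clone count, total reads, proportions.

    ``table`` maps sample id to a list of (clone_id, read_count) pairs.
    Empty samples yield zero counts with ``empty=True``.
    """
    rows = []
    for sample, clones in table.items():
        ids = [c for c, _ in clones]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate clone ids in sample {sample!r}")
        reads = np.array([r for _, r in clones], dtype=float)
        if len(reads) and (reads < 1).any():
            raise ValidationError(f"read counts must be >= 1 in sample {sample!r}")
        total = float(reads.sum())
        rows.append(
            {
                "sample_id": sample,
                "n_clones": len(clones),
                "total_reads": int(total),
                "proportions": dict(zip(ids, (reads / total).tolist())) if total else {},
                "empty": len(clones) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
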