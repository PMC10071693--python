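"""Core domain types: expression matrices, gene signatures, IHC annotations.

Expression data are dense gene-by-sample TPM matrices held in a pandas
DataFrame (genes as rows, samples as columns).  All values must be finite
and non-negative; gene and sample identifiers must be unique.  Gene
identifiers are HGNC symbols after alias canonicalisation (see
:mod:`ipass.aliases`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

IHC_CLASSES = ("cold", "altered", "hot", "indeterminate")


class ExpressionMatrix:
    """A validated genes x samples TPM matrix.

    Parameters
    ----------
    data
        DataFrame with gene symbols as index and sample identifiers as
        columns.  Values are TPM (non-negative, finite).
    """

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid expression value {values[i, j]!r} at gene "
                f"{data.index[i]!r}, sample {data.columns[j]!r} "
                "(TPM must be finite and >= 0)"
            )
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class GeneSignature:
    """An ordered gene set, optionally carrying importance scores.

    ``rank_scores``, when present, are the per-gene importances that
    produced the ordering and must be non-increasing.
    """

    name: str
    genes: tuple[str, ...]
    rank_scores: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if self.rank_scores is not None:
            scores = tuple(float(s) for s in self.rank_scores)
            object.__setattr__(self, "rank_scores", scores)
            if len(scores) != len(self.genes):
                raise ValidationError("rank_scores length != number of genes")
            if any(s < 0 for s in scores):
                raise ValidationError("rank_scores must be non-negative")
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValidationError("rank_scores must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class IHCAnnotation:
    """Per-sample pathologist annotation.

    ``ihc_class`` is the CD8/CD4 infiltration call: *cold* (few or absent
    T-cells), *altered* (moderate or peripherally restricted), *hot*
    (widespread intratumoural T-cells), or *indeterminate*.  Cell densities
    are cells per mm^2; ``pdl1_percent`` is percentage of cells with
    membranous PD-L1 staining.
    """

    sample_id: str
    ihc_class: str
    cd45_density: float | None = None
    cd8_density: float | None = None
    cd4_density: float | None = None
    pdl1_percent: float | None = None

    def __post_init__(self):
        if self.ihc_class not in IHC_CLASSES:
            raise ValidationError(
                f"ihc_class {self.ihc_class!r} not one of {IHC_CLASSES}"
            )
        for name in ("cd45_density", "cd8_density", "cd4_density"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be non-negative, got {v!r}")
        if self.pdl1_percent is not None and not (0 <= self.pdl1_percent <= 100):
            raise ValidationError(
                f"pdl1_percent must be in [0, 100], got {self.pdl1_percent!r}"
            )
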