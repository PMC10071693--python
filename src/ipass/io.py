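"""Readers and writers for the package's text formats.

- Expression matrices: TSV, genes as rows (first column = gene symbol,
  header row = sample ids).  A ``transpose`` flag accepts samples-as-rows
  exports.
- Gene panels: one symbol per line, ``#`` comments allowed.
- IHC annotations: TSV with ``sample_id`` and ``ihc_class`` columns plus
  optional density/percentage columns.
- Signature + calibration: a single JSON document, so scoring is fully
  reproducible from one artifact.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .aliases import GeneAliasMap, default_alias_map
from .datamodel import ExpressionMatrix, GeneSignature, IHCAnnotation
from .errors import FormatError
from .scoring import ScoreCalibration

_ANNOTATION_OPTIONAL = ("cd45_density", "cd8_density", "cd4_density", "pdl1_percent")


def read_expression_matrix(
    path,
    alias_map: GeneAliasMap | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a TSV TPM matrix and canonicalise gene symbols.

    Two input genes that collapse onto the same canonical symbol are an
    error — the caller must resolve which row to keep.
    """
    alias_map = alias_map if alias_map is not None else default_alias_map()
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if transpose:
        df = df.T
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise FormatError(
            f"non-numeric expression values in sample column(s) {list(non_numeric)}"
        )
    canonical = alias_map.canonicalise([str(g) for g in df.index])
    dup = pd.Index(canonical).duplicated(keep=False)
    if dup.any():
        pairs = sorted(
            {(orig, canon) for orig, canon, d in zip(df.index, canonical, dup) if d}
        )
        raise FormatError(
            "duplicate genes after alias canonicalisation: "
            + "; ".join(f"{o} -> {c}" for o, c in pairs)
        )
    df.index = pd.Index(canonical, name=df.index.name or "gene")
    df.columns = [str(c) for c in df.columns]
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments skipped."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_annotations(path) -> list[IHCAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "ihc_class"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in annotations: {dups}")
    out = []
    for _, row in df.iterrows():
        extra = {
            k: (None if pd.isna(row[k]) else float(row[k]))
            for k in _ANNOTATION_OPTIONAL
            if k in df.columns
        }
        out.append(IHCAnnotation(str(row["sample_id"]), str(row["ihc_class"]), **extra))
    return out


def write_annotations(annotations: list[IHCAnnotation], path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "ihc_class": a.ihc_class,
                **{k: getattr(a, k) for k in _ANNOTATION_OPTIONAL},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_signature(sig: GeneSignature, calib: ScoreCalibration, path) -> None:
    """Serialise a signature + calibration to one JSON artifact (sorted keys,
    so writes are byte-deterministic)."""
    doc = {
        "signature": {
            "name": sig.name,
            "genes": list(sig.genes),
            **(
                {"rank_scores": list(sig.rank_scores)}
                if sig.rank_scores is not None
                else {}
            ),
        },
        "calibration": {
            "raw_min": calib.raw_min,
            "raw_max": calib.raw_max,
            "norm_threshold": calib.norm_threshold,
            "raw_threshold": calib.raw_threshold,
            "log_base": calib.log_base,
            "pseudocount": calib.pseudocount,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_signature(path) -> tuple[GeneSignature, ScoreCalibration]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse signature file {path}: {exc}") from exc
    try:
        s = doc["signature"]
        c = doc["calibration"]
        sig = GeneSignature(
            name=s["name"],
            genes=tuple(s["genes"]),
            rank_scores=tuple(s["rank_scores"]) if "rank_scores" in s else None,
        )
        calib = ScoreCalibration(
            raw_min=float(c["raw_min"]),
            raw_max=float(c["raw_max"]),
            norm_threshold=float(c["norm_threshold"]),
            raw_threshold=float(c["raw_threshold"]),
            log_base=float(c["log_base"]),
            pseudocount=float(c["pseudocount"]),
        )
    except KeyError as exc:
        raise FormatError(f"signature file {path} missing field {exc}") from exc
    return sig, calib


def load_default_signature() -> tuple[GeneSignature, ScoreCalibration]:
    """The packaged default signature + calibration artifact.

    The gene list is synthetic — the derivation output on the packaged
    synthetic fixture cohort (the published gene ranking is not
    reproducible without the controlled-access cohorts).  The calibration
    is the shipped surrogate whose endpoints satisfy the published
    threshold pair (raw 0.83 <-> normalised -0.25).
    """
    ref = resources.files("ipass.data") / "default_signature_synthetic.json"
    with resources.as_file(ref) as p:
        return read_signature(p)
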