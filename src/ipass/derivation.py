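"""Signature derivation from an IHC-labelled cohort.

Pipeline: merge the pathologist's hot/altered calls into a single
*inflamed* class (cold stays cold, indeterminate samples are dropped);
restrict the expression matrix to the immune panel; split the labelled
samples into stratified train/test halves; train a Gini-impurity random
forest on log2(TPM+1) training expression; rank genes by mean decrease in
Gini and keep the top k (default 15); score the full supplied cohort with
the resulting signature; fit the min-max calibration on those scores; and
evaluate classification of the held-out test samples against their IHC
labels.

The whole derivation is a pure function of (matrix, annotations, config):
rerunning with the same seed reproduces the report bit for bit.  Test
samples never touch training or the importance ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datamodel import ExpressionMatrix, GeneSignature, IHCAnnotation
from .errors import IpassError, ValidationError
from .evaluation import MetricsReport, confusion, metrics
from .scoring import (
    LABEL_COLD,
    LABEL_INFILTRATED,
    ScoreCalibration,
    classify,
    compute_raw_score,
    fit_calibration,
    normalize_score,
)

log = logging.getLogger(__name__)

LABEL_INFLAMED = "inflamed"


@dataclass(frozen=True)
class DerivationConfig:
    """Settings for signature derivation.

    Forest defaults (500 trees, sqrt(p) features per split, unlimited
    depth, Gini impurity) are the conventional random-forest defaults for
    classification.
    """

    k_genes: int = 15
    train_fraction: float = 0.5
    n_trees: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0
    inflamed_classes: frozenset[str] = frozenset({"hot", "altered"})
    norm_threshold: float = -0.25
    log_base: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.k_genes < 1:
            raise ValidationError("k_genes must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        object.__setattr__(self, "inflamed_classes", frozenset(self.inflamed_classes))


@dataclass(frozen=True)
class DerivationReport:
    signature: GeneSignature
    calibration: ScoreCalibration
    importances: dict[str, float]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_metrics: MetricsReport
    config: DerivationConfig
    raw_scores: dict[str, float] = field(default_factory=dict)
    norm_scores: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)


def merge_ihc_labels(
    annotations: list[IHCAnnotation],
    inflamed_classes=frozenset({"hot", "altered"}),
) -> dict[str, str]:
    """Binary labels: hot/altered -> inflamed, cold -> cold; indeterminate
    samples are excluded (count logged)."""
    labels: dict[str, str] = {}
    n_dropped = 0
    for a in annotations:
        if a.ihc_class == "indeterminate":
            n_dropped += 1
        elif a.ihc_class in inflamed_classes:
            labels[a.sample_id] = LABEL_INFLAMED
        else:
            labels[a.sample_id] = "cold"
    if n_dropped:
        log.warning("excluded %d indeterminate sample(s)", n_dropped)
    if not labels:
        raise IpassError("no samples left after excluding indeterminate annotations")
    return labels


def filter_panel_genes(matrix: ExpressionMatrix, panel) -> ExpressionMatrix:
    """Restrict the matrix to panel genes, preserving matrix gene order."""
    panel = set(panel)
    present = [g for g in matrix.gene_ids if g in panel]
    n_missing = len(panel) - len(present)
    if not present:
        raise IpassError("no panel genes present in the expression matrix")
    if n_missing:
        log.info("%d panel gene(s) absent from the matrix", n_missing)
    return matrix.subset_genes(present)


def stratified_split(
    labels: dict[str, str], train_fraction: float, seed: int
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Per-class stratified split with largest-remainder rounding.

    The overall training size is floor(n * train_fraction), so for an odd
    cohort the test set receives the extra sample.  Per-class training
    counts are the largest-remainder apportionment of that total; ties in
    remainder go to the larger class (then alphabetical class name).
    Sample membership within each class is a seeded uniform draw.
    """
    classes = sorted(set(labels.values()))
    by_class = {c: sorted(s for s, l in labels.items() if l == c) for c in classes}
    for c, members in by_class.items():
        if len(members) < 2:
            raise IpassError(f"class {c!r} has {len(members)} sample(s); cannot stratify")
    n_total = len(labels)
    n_train = math.floor(n_total * train_fraction)
    targets = {c: len(by_class[c]) * train_fraction for c in classes}
    counts = {c: math.floor(targets[c]) for c in classes}
    leftover = n_train - sum(counts.values())
    order = sorted(
        classes,
        key=lambda c: (-(targets[c] - counts[c]), -len(by_class[c]), c),
    )
    for c in order[:leftover]:
        counts[c] += 1
    for c in classes:
        counts[c] = min(max(counts[c], 1), len(by_class[c]) - 1)

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for c in classes:
        members = np.array(by_class[c])
        rng.shuffle(members)
        train.extend(members[: counts[c]])
        test.extend(members[counts[c]:])
    if not train or not test:
        raise IpassError("train_fraction produced an empty train or test set")
    return tuple(sorted(train)), tuple(sorted(test))


def _log_expression(matrix: ExpressionMatrix, log_base: float, pseudocount: float):
    return np.log(matrix.values + pseudocount) / math.log(log_base)


def train_classifier(
    train_matrix: ExpressionMatrix,
    train_labels: dict[str, str],
    config: DerivationConfig,
) -> tuple[RandomForestClassifier, dict[str, float]]:
    """Fit a Gini random forest on log-expression; return (forest, per-gene
    mean-decrease-in-Gini importances)."""
    y = np.array([train_labels[s] for s in train_matrix.sample_ids])
    if len(set(y)) < 2:
        raise IpassError("training labels contain a single class")
    if min(np.sum(y == c) for c in set(y)) < 2:
        raise IpassError("each class needs >= 2 training samples")
    X = _log_expression(train_matrix, config.log_base, config.pseudocount).T
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=config.max_features,
        random_state=config.seed,
    )
    forest.fit(X, y)
    importances = dict(zip(train_matrix.gene_ids, forest.feature_importances_.tolist()))
    return forest, importances


def extract_signature(
    importances: dict[str, float], k_genes: int, name: str = "derived"
) -> GeneSignature:
    """Top-k genes by importance; ties broken by lexicographic gene symbol."""
    if k_genes > len(importances):
        raise IpassError(
            f"k_genes={k_genes} exceeds the {len(importances)} genes with importances"
        )
    ranked = sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))[:k_genes]
    return GeneSignature(
        name=name,
        genes=tuple(g for g, _ in ranked),
        rank_scores=tuple(v for _, v in ranked),
    )


def derive_ipass(
    matrix: ExpressionMatrix,
    annotations: list[IHCAnnotation],
    panel,
    config: DerivationConfig | None = None,
    calibration_matrix: ExpressionMatrix | None = None,
) -> DerivationReport:
    """End-to-end signature derivation; see the module docstring.

    ``calibration_matrix`` optionally supplies a larger cohort for fitting
    the min-max calibration (the signature itself always comes from the
    labelled cohort); by default calibration uses all samples of ``matrix``.
    """
    config = config if config is not None else DerivationConfig()
    labels = merge_ihc_labels(annotations, config.inflamed_classes)
    missing = sorted(set(labels) - set(matrix.sample_ids))
    if missing:
        raise IpassError(f"labelled samples absent from matrix: {missing[:5]}")
    panel_matrix = filter_panel_genes(matrix, panel)
    train_ids, test_ids = stratified_split(labels, config.train_fraction, config.seed)
    _, importances = train_classifier(
        panel_matrix.subset_samples(train_ids), labels, config
    )
    signature = extract_signature(importances, config.k_genes, name="ipass_derived")

    score_matrix = calibration_matrix if calibration_matrix is not None else matrix
    raw = compute_raw_score(score_matrix, signature)
    calibration = fit_calibration(
        raw.to_numpy(),
        norm_threshold=config.norm_threshold,
        log_base=config.log_base,
        pseudocount=config.pseudocount,
    )
    cohort_raw = compute_raw_score(matrix, signature, calibration)
    norm = normalize_score(cohort_raw.to_numpy(), calibration)
    pred = dict(zip(cohort_raw.index, classify(norm, calibration)))

    truth_binary = {
        s: (LABEL_INFILTRATED if labels[s] == LABEL_INFLAMED else LABEL_COLD)
        for s in test_ids
    }
    cm = confusion(
        {s: pred[s] for s in test_ids}, truth_binary, positive=LABEL_INFILTRATED
    )
    return DerivationReport(
        signature=signature,
        calibration=calibration,
        importances=importances,
        train_ids=train_ids,
        test_ids=test_ids,
        test_metrics=metrics(cm),
        config=config,
        raw_scores={s: float(v) for s, v in cohort_raw.items()},
        norm_scores=dict(zip(cohort_raw.index, (float(v) for v in norm))),
        labels=pred,
    )
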