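"""Classification metrics, association tests and immune-gene clustering.

Conventions:

- The positive class of every confusion matrix is the inflamed /
  t_cell_infiltrated call.
- Fisher's exact test is two-sided by the probability-mass rule (sum the
  hypergeometric probabilities of all tables no more probable than the
  observed one) — the R convention.  A doubling rule would give different
  p-values.
- The two-group comparison follows the standard decision flow: Shapiro-Wilk
  normality on each group and an F-test for equal variances at alpha=0.05;
  if normality is rejected in either group or the variances differ, the
  Wilcoxon rank-sum test is used, otherwise the pooled two-sample t-test.
- Percentages are reported to the whole percent with round-half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix
from .errors import IpassError, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation; positive class = inflamed/t_cell_infiltrated."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion-matrix cells must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Diagnostic metrics; a metric with a zero denominator is None and its
    name is listed in ``undefined`` rather than silently reported as 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    n: int
    undefined: tuple[str, ...] = ()


def round_half_up_percent(fraction: float) -> int:
    """0.885 -> 89, matching conventional clinical reporting."""
    return int(math.floor(fraction * 100 + 0.5))


def confusion(pred: dict[str, str], truth: dict[str, str], positive: str) -> ConfusionMatrix:
    """Cross-tabulate per-sample predicted vs true labels."""
    if set(pred) != set(truth):
        raise IpassError(
            f"prediction/truth sample ids differ: {sorted(set(pred) ^ set(truth))[:5]}"
        )
    tp = fn = fp = tn = 0
    for s in pred:
        p, t = pred[s] == positive, truth[s] == positive
        if p and t:
            tp += 1
        elif not p and t:
            fn += 1
        elif p and not t:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    if cm.n == 0:
        raise IpassError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den else None

    vals = {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn) / cm.n,
    }
    undefined = tuple(k for k, v in vals.items() if v is None)
    return MetricsReport(n=cm.n, undefined=undefined, **vals)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value (probability-mass rule)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0:
        raise IpassError("all-zero 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise IpassError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise IpassError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def two_group_compare(a, b, alpha: float = 0.05) -> tuple[str, float, float]:
    """Compare two samples, choosing the test by the normality/variance flow.

    Returns ``(test_name, statistic, p)`` where ``test_name`` is
    ``"t-test"`` or ``"wilcoxon"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise IpassError("each group needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise IpassError("both groups are constant; no test is meaningful")
    normal = all(
        np.ptp(g) > 0 and stats.shapiro(g).pvalue >= alpha for g in (a, b)
    )
    # two-sided F-test on the variance ratio
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va > 0 and vb > 0:
        f = va / vb
        cdf = stats.f.cdf(f, a.size - 1, b.size - 1)
        equal_var = 2 * min(cdf, 1 - cdf) >= alpha
    else:
        equal_var = False
    if normal and equal_var:
        res = stats.ttest_ind(a, b, equal_var=True)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "wilcoxon", float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GeneClusterResult:
    assignments: dict[str, int]
    cluster_mean_r: dict[int, float]
    top_cluster: int


def cluster_genes_vs_score(
    matrix: ExpressionMatrix,
    gene_list,
    scores,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> GeneClusterResult:
    """K-means cluster immune genes and find the cluster tracking the score.

    Genes are standardised (per-gene z of log2(TPM+1) across samples)
    before k-means with seeded k-means++ initialisation and ``n_restarts``
    restarts.  For each cluster the mean Pearson r between member-gene
    log-expression and the per-sample scores is computed; the argmax
    cluster is reported.
    """
    genes = [g for g in gene_list if g in matrix.data.index]
    if not genes:
        raise IpassError("none of the requested genes are in the matrix")
    if not 2 <= k <= len(genes):
        raise IpassError(f"k={k} must be in [2, {len(genes)}]")
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(matrix.sample_ids):
        raise IpassError("scores must align with the matrix samples")
    logx = np.log2(matrix.data.loc[genes].to_numpy() + 1.0)
    sd = logx.std(axis=1, ddof=0)
    if (sd == 0).any():
        flat = [g for g, s in zip(genes, sd) if s == 0]
        raise IpassError(f"constant-expression gene(s) cannot be standardised: {flat[:5]}")
    z = (logx - logx.mean(axis=1, keepdims=True)) / sd[:, None]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    assignments = dict(zip(genes, labels.tolist()))
    cluster_mean_r: dict[int, float] = {}
    for c in sorted(set(labels.tolist())):
        rs = [pearson_r(logx[i], scores)[0] for i in np.flatnonzero(labels == c)]
        cluster_mean_r[c] = float(np.mean(rs))
    top = max(sorted(cluster_mean_r), key=lambda c: cluster_mean_r[c])
    return GeneClusterResult(assignments, cluster_mean_r, top)


def metrics_table(report: MetricsReport) -> pd.DataFrame:
    """Whole-percent presentation of a metrics report."""
    rows = []
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        v = getattr(report, name)
        rows.append(
            {
                "metric": name,
                "value": v,
                "percent": None if v is None else round_half_up_percent(v),
            }
        )
    return pd.DataFrame(rows)
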