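"""Seeded synthetic cohorts with planted immune structure.

The generator emulates the cohort shape the derivation pipeline assumes: a
bulk RNA-seq TPM matrix where a small set of informative immune genes is
over-expressed in inflamed (hot/altered) samples relative to cold samples.

Model: per-gene baseline b_g ~ Normal(baseline_log2_mean, baseline_log2_sd)
in log2(TPM+1) space; sample s of class c expresses gene g at

    x_gs = b_g + delta_c * 1[g informative] + Normal(0, noise_sd)

with delta_hot = effect_hot, delta_altered = effect_altered, delta_cold = 0,
and TPM = max(2^x - 1, 0).  The -1 offset mirrors the scoring pseudocount,
so planted log2 effects translate directly into IPASS separation.  The
altered class gets an intermediate effect because the inflamed group the
classifier learns merges hot and altered samples.

What this does *not* emulate: tumour-type-specific expression profiles,
gene-gene correlation structure, library-size artefacts or dropout.
Recovery results on these cohorts are a best-case read-out of the pipeline,
not of real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, IHCAnnotation
from .errors import ValidationError

#: Fixed seed of the packaged fixture cohort (arbitrary constant).
FIXTURE_SEED = 230415


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; defaults mirror the derivation cohort
    (~70 IHC-labelled samples, 766-gene immune panel, 15 informative genes)."""

    n_cold: int = 45
    n_altered: int = 13
    n_hot: int = 12
    n_genes: int = 1000
    n_panel: int = 766
    n_informative: int = 15
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    effect_hot: float = 2.0
    effect_altered: float = 1.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (self.n_informative <= self.n_panel <= self.n_genes):
            raise ValidationError(
                "need n_informative <= n_panel <= n_genes, got "
                f"{self.n_informative}/{self.n_panel}/{self.n_genes}"
            )
        if min(self.n_cold, self.n_altered, self.n_hot) < 0:
            raise ValidationError("class counts must be >= 0")
        if self.n_cold + self.n_altered + self.n_hot < 4:
            raise ValidationError("total cohort size must be >= 4")
        if self.baseline_log2_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    matrix: ExpressionMatrix
    annotations: list[IHCAnnotation]
    informative_genes: tuple[str, ...]
    panel: tuple[str, ...]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not set(self.informative_genes) <= set(self.panel):
            raise ValidationError("informative genes must be a subset of the panel")


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_cold + config.n_altered + config.n_hot
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    classes = (
        ["cold"] * config.n_cold
        + ["altered"] * config.n_altered
        + ["hot"] * config.n_hot
    )
    rng.shuffle(classes)

    panel = tuple(str(g) for g in rng.choice(genes, size=config.n_panel, replace=False))
    informative = tuple(
        sorted(str(g) for g in rng.choice(panel, size=config.n_informative, replace=False))
    )
    info_mask = np.isin(genes, informative)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    effects = {"cold": 0.0, "altered": config.effect_altered, "hot": config.effect_hot}
    shift = np.array([effects[c] for c in classes])  # per sample
    log2_tpm = (
        baseline[:, None]
        + info_mask[:, None] * shift[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    )
    tpm = np.maximum(np.exp2(log2_tpm) - 1.0, 0.0)

    # Plausible CD8 IHC densities, increasing with inflammation.
    density_mu = {"cold": 2.0, "altered": 4.0, "hot": 5.5}
    cd8 = np.exp(rng.normal([density_mu[c] for c in classes], 0.5))

    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples))
    annotations = [
        IHCAnnotation(sample_id=s, ihc_class=c, cd8_density=float(d))
        for s, c, d in zip(samples, classes, cd8)
    ]
    return SyntheticCohort(
        matrix=matrix,
        annotations=annotations,
        informative_genes=informative,
        panel=tuple(sorted(panel)),
        classes=dict(zip(samples, classes)),
    )


def fixture_config(seed: int = FIXTURE_SEED) -> SimulationConfig:
    """Configuration of the packaged fixture cohort (default generator
    settings at a fixed seed)."""
    return SimulationConfig(seed=seed)


def fixture_cohort() -> SyntheticCohort:
    return simulate_cohort(fixture_config())


def recovery_config(seed: int) -> SimulationConfig:
    """The planted-signal recovery benchmark: 70 samples (25 inflamed /
    45 cold), 766-gene panel, a common 1.5 log2-unit effect for both
    inflamed classes."""
    return replace(
        SimulationConfig(seed=seed), effect_hot=1.5, effect_altered=1.5
    )


def simulate_epitopes(
    n_mutations: int,
    epitopes_per_mutation: int,
    pass_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, int]:
    """Epitope-prediction table with known ground truth.

    Each mutation is designated passing or failing up front; passing
    mutations get at least one row satisfying all three neoantigen cut-offs
    (mutant IC50 < 500 nM, wild-type IC50 > 500 nM, gene TPM > 1), failing
    mutations get rows that each violate at least one cut-off, straddling
    the boundaries.  Returns (table, expected neoantigen count).
    """
    if n_mutations < 0 or epitopes_per_mutation <= 0:
        raise ValidationError("n_mutations >= 0 and epitopes_per_mutation > 0 required")
    if not 0 <= pass_fraction <= 1:
        raise ValidationError("pass_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(round(pass_fraction * n_mutations))
    passing = set(rng.choice(n_mutations, size=n_pass, replace=False)) if n_mutations else set()
    alleles = ["HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-C*07:01"]
    rows = []
    for m in range(n_mutations):
        mut_id = f"MUT{m + 1:05d}"
        tpm = float(rng.uniform(1.5, 50))  # gene-level expression, shared per mutation
        for e in range(epitopes_per_mutation):
            allele = alleles[int(rng.integers(len(alleles)))]
            if m in passing and e == 0:
                # guaranteed passing epitope
                mut, wt = rng.uniform(10, 480), rng.uniform(520, 5000)
            elif m in passing:
                # free draw near the boundaries; may or may not pass
                mut, wt = rng.uniform(300, 700), rng.uniform(300, 700)
            else:
                # force failure of one randomly chosen cut-off
                fail = int(rng.integers(3))
                mut = rng.uniform(520, 5000) if fail == 0 else rng.uniform(10, 480)
                wt = rng.uniform(10, 480) if fail == 1 else rng.uniform(520, 5000)
                row_tpm = rng.uniform(0, 0.9) if fail == 2 else tpm
                rows.append((mut_id, allele, float(mut), float(wt), float(row_tpm)))
                continue
            rows.append((mut_id, allele, float(mut), float(wt), tpm))
    table = pd.DataFrame(
        rows, columns=["mutation_id", "hla_allele", "mut_ic50", "wt_ic50", "gene_tpm"]
    )
    return table, n_pass
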