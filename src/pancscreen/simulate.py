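"""Synthetic multi-cancer cohorts with planted, recorded effects.

The generator emulates the statistical structure the screening pipeline
assumes in real pan-cancer data: several cancer types, each with a healthy
and a tumor arm of log-normalized expression; one focal gene downshifted in
every tumor arm; per-tumor-sample aneuploidy scores negatively coupled to
the focal gene; Poisson somatic mutation counts with the focal gene's rate
depleted; one transcription-factor target set whose members co-express with
the focal gene in tumors only (a shared latent factor); promoter-probe
methylation betas; and a separate oncogene-overexpression experiment with
empty-vector controls.

Every planted parameter, together with the realized per-cancer effect sizes,
is recorded in a :class:`CohortTruth` so downstream tests are
parameter-recovery tests rather than golden-file comparisons.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    HEALTHY,
    TUMOR,
    validate_gene_annotation,
    validate_methylation_table,
    validate_mutation_table,
    validate_sample_table,
)

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "OverexpressionConfig",
    "generate_overexpression_experiment",
]

MUTATION_EFFECT_CLASSES = ("coding", "utr")


@dataclass(frozen=True)
class CohortConfig:
    """Planted parameters of a synthetic pan-cancer cohort.

    Defaults mirror the cohort structure the screen targets: 13 cancer types
    with 25 healthy + 25 tumor samples each, 2000 genes, a focal-gene
    downshift of -1.5 log2 units in every tumor arm, a target Spearman
    correlation of -0.3 between focal expression and tumor aneuploidy,
    integer aneuploidy scores on 0..39, 20 transcription-factor target sets
    of 25-200 genes with one tumor-only rewired set (latent-factor weight
    0.6), somatic mutations at 0.02 events per kb per tumor sample with the
    focal gene's rate multiplied by 0.2, and Beta(2, 5) promoter methylation.
    """

    n_cancers: int = 13
    n_healthy: int = 25
    n_tumor: int = 25
    n_genes: int = 2000
    focal_gene: str | None = None  # default: first gene of the universe
    focal_downshift: float = -1.5
    baseline_mean_range: tuple[float, float] = (1.0, 10.0)
    baseline_sd: float = 1.0
    aneuploidy_coupling: float = -0.3
    aneuploidy_range: tuple[int, int] = (0, 39)
    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (25, 200)
    rewired_set: str = "TF01"
    rewiring_weight: float = 0.6
    mutation_base_rate: float = 0.02  # events per kb per tumor sample
    focal_depletion_factor: float = 0.2
    gene_length_range_bp: tuple[int, int] = (500, 100_000)
    effect_class_probs: tuple[float, ...] = (0.8, 0.2)  # coding, utr
    n_probes_per_gene: int = 3
    probe_window_bp: int = 2000
    methylation_beta_shape: tuple[float, float] = (2.0, 5.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 1 or self.n_tumor < 1:
            raise ValueError("each arm needs at least one sample")
        if not abs(self.aneuploidy_coupling) < 1:
            raise ValueError("|aneuploidy_coupling| must be < 1")
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if self.focal_gene is None:
            object.__setattr__(self, "focal_gene", self.gene_ids[0])
        elif self.focal_gene not in self.gene_ids:
            raise ValueError(f"focal_gene {self.focal_gene!r} not in gene universe")
        if self.set_size_range[1] >= self.n_genes:
            raise ValueError("gene sets must be smaller than the gene universe")
        if self.focal_depletion_factor < 0:
            raise ValueError("focal_depletion_factor must be >= 0")
        if abs(sum(self.effect_class_probs) - 1.0) > 1e-9:
            raise ValueError("effect_class_probs must sum to 1")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def cancer_types(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cancers)]


@dataclass
class CohortTruth:
    """Planted parameters plus realized effect sizes of one generated cohort."""

    config: CohortConfig
    rewired_members: list[str] = field(default_factory=list)
    realized_focal_shift: dict[str, float] = field(default_factory=dict)
    realized_aneuploidy_rho: dict[str, float] = field(default_factory=dict)
    realized_aneuploidy_rho_median: float = float("nan")
    focal_length_bp: int = 0

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"] = dataclasses.asdict(self.config)
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


@dataclass
class SyntheticCohort:
    """Bundle of all tables produced by :func:`generate_cohort`."""

    expression: ExpressionMatrix
    samples: pd.DataFrame
    mutations: pd.DataFrame
    methylation: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: CohortTruth


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with given Spearman rho.

    For a bivariate Gaussian, rho_s = (6/pi) * asin(r/2); inverting gives
    r = 2*sin(pi*rho_s/6). Used to calibrate the latent aneuploidy noise so
    the realized rank correlation hits the configured target.
    """
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _make_annotation(config: CohortConfig) -> pd.DataFrame:
    rng = child_rng(config.rng_seed, "annotation")
    lo, hi = config.gene_length_range_bp
    lengths = np.round(
        10 ** rng.uniform(np.log10(lo), np.log10(hi), size=config.n_genes)
    ).astype(int)
    ann = pd.DataFrame(
        {
            "gene_id": config.gene_ids,
            "length_bp": lengths,
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, size=config.n_genes)],
            "tss": rng.integers(10_000, 100_000_000, size=config.n_genes),
            "strand": rng.choice(["+", "-"], size=config.n_genes),
        }
    )
    return validate_gene_annotation(ann)


def _make_gene_sets(config: CohortConfig) -> GeneSetCollection:
    rng = child_rng(config.rng_seed, "gene_sets")
    genes = [g for g in config.gene_ids if g != config.focal_gene]
    sets: dict[str, list[str]] = {}
    lo, hi = config.set_size_range
    for i in range(config.n_gene_sets):
        name = f"TF{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False).tolist()
        sets[name] = members
    if config.rewired_set not in sets:
        raise ValueError(f"rewired_set {config.rewired_set!r} not among generated sets")
    return GeneSetCollection(sets, {n: "synthetic TF target set" for n in sets})


def _make_samples(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for cancer in config.cancer_types:
        for i in range(config.n_healthy):
            rows.append((f"{cancer}_H{i + 1:03d}", cancer, HEALTHY))
        for i in range(config.n_tumor):
            rows.append((f"{cancer}_T{i + 1:03d}", cancer, TUMOR))
    samples = pd.DataFrame(rows, columns=["sample_id", "cancer_type", "sample_class"])
    samples["aneuploidy_score"] = np.nan
    return samples


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one synthetic pan-cancer cohort; deterministic given rng_seed."""
    config = config or CohortConfig()
    annotation = _make_annotation(config)
    gene_sets = _make_gene_sets(config)
    samples = _make_samples(config)
    truth = CohortTruth(
        config=config,
        rewired_members=sorted(gene_sets[config.rewired_set]),
        focal_length_bp=int(
            annotation.set_index("gene_id").loc[config.focal_gene, "length_bp"]
        ),
    )

    genes = config.gene_ids
    sample_ids = samples["sample_id"].tolist()
    n_samples = len(sample_ids)
    is_tumor = (samples["sample_class"] == TUMOR).to_numpy()
    focal_idx = genes.index(config.focal_gene)

    rng = child_rng(config.rng_seed, "expression")
    mu = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    values = mu[:, None] + rng.normal(0.0, config.baseline_sd, (config.n_genes, n_samples))
    values[focal_idx, is_tumor] += config.focal_downshift

    # Tumor-only latent factor shared by the focal gene and the rewired set.
    rng_latent = child_rng(config.rng_seed, "rewiring")
    latent = rng_latent.normal(0.0, 1.0, size=int(is_tumor.sum()))
    member_idx = [genes.index(g) for g in truth.rewired_members]
    if config.rewiring_weight != 0.0:
        values[focal_idx, is_tumor] += config.rewiring_weight * latent
        values[np.ix_(member_idx, is_tumor)] += config.rewiring_weight * latent
    values = np.clip(values, 0.0, None)
    expression = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))

    # Aneuploidy scores: affine in the focal gene's standardized tumor
    # expression plus calibrated Gaussian noise, rounded and clamped.
    rng_aneu = child_rng(config.rng_seed, "aneuploidy")
    r = spearman_to_pearson(config.aneuploidy_coupling)
    lo, hi = config.aneuploidy_range
    center, scale = (lo + hi) / 2.0, (hi - lo) / 5.0
    scores = np.full(n_samples, np.nan)
    for cancer in config.cancer_types:
        mask = ((samples["cancer_type"] == cancer) & (samples["sample_class"] == TUMOR)).to_numpy()
        focal_expr = values[focal_idx, mask]
        sd = focal_expr.std()
        z = (focal_expr - focal_expr.mean()) / sd if sd > 0 else np.zeros(mask.sum())
        lat = r * z + np.sqrt(1 - r**2) * rng_aneu.normal(size=int(mask.sum()))
        cancer_scores = np.clip(np.round(center + scale * lat), lo, hi)
        scores[mask] = cancer_scores
        rho = stats.spearmanr(focal_expr, cancer_scores).statistic
        truth.realized_aneuploidy_rho[cancer] = float(rho)
        healthy_mask = (
            (samples["cancer_type"] == cancer) & (samples["sample_class"] == HEALTHY)
        ).to_numpy()
        truth.realized_focal_shift[cancer] = float(
            values[focal_idx, mask].mean() - values[focal_idx, healthy_mask].mean()
        )
    samples = samples.assign(aneuploidy_score=scores)
    truth.realized_aneuploidy_rho_median = float(
        np.median(list(truth.realized_aneuploidy_rho.values()))
    )

    mutations = _make_mutations(config, annotation, samples)
    methylation = _make_methylation(config, annotation, sample_ids)

    return SyntheticCohort(
        expression=expression,
        samples=validate_sample_table(samples),
        mutations=mutations,
        methylation=methylation,
        annotation=annotation,
        gene_sets=gene_sets,
        truth=truth,
    )


def _make_mutations(
    config: CohortConfig, annotation: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    rng = child_rng(config.rng_seed, "mutations")
    lengths_kb = annotation["length_bp"].to_numpy() / 1000.0
    n_samples = config.n_healthy + config.n_tumor  # per-cancer cohort size
    rate = config.mutation_base_rate * lengths_kb * n_samples
    focal_idx = annotation.index[annotation["gene_id"] == config.focal_gene][0]
    rate = rate.copy()
    rate[focal_idx] *= config.focal_depletion_factor

    gene_ids = annotation["gene_id"].to_numpy()
    records: list[pd.DataFrame] = []
    for cancer in config.cancer_types:
        tumor_ids = samples.loc[
            (samples["cancer_type"] == cancer) & (samples["sample_class"] == TUMOR),
            "sample_id",
        ].to_numpy()
        counts = rng.poisson(rate)
        total = int(counts.sum())
        if total == 0:
            continue
        gene_col = np.repeat(gene_ids, counts)
        records.append(
            pd.DataFrame(
                {
                    "gene_id": gene_col,
                    "sample_id": rng.choice(tumor_ids, size=total),
                    "cancer_type": cancer,
                    "effect_class": rng.choice(
                        MUTATION_EFFECT_CLASSES, size=total, p=config.effect_class_probs
                    ),
                }
            )
        )
    if not records:
        mutations = pd.DataFrame(
            columns=["gene_id", "sample_id", "cancer_type", "effect_class"]
        )
    else:
        mutations = pd.concat(records, ignore_index=True)
    return validate_mutation_table(mutations)


def _make_methylation(
    config: CohortConfig, annotation: pd.DataFrame, sample_ids: list[str]
) -> pd.DataFrame:
    rng = child_rng(config.rng_seed, "methylation")
    n_probes = config.n_genes * config.n_probes_per_gene
    offsets = rng.integers(
        -config.probe_window_bp, config.probe_window_bp + 1, size=n_probes
    )
    tss = np.repeat(annotation["tss"].to_numpy(), config.n_probes_per_gene)
    chrom = np.repeat(annotation["chrom"].to_numpy(), config.n_probes_per_gene)
    positions = np.maximum(tss + offsets, 0)
    a, b = config.methylation_beta_shape
    betas = rng.beta(a, b, size=(n_probes, len(sample_ids)))
    meth = pd.DataFrame(
        {
            "probe_id": [f"cg{i + 1:06d}" for i in range(n_probes)],
            "chrom": chrom,
            "position": positions,
        }
    )
    meth = pd.concat(
        [meth, pd.DataFrame(betas, columns=sample_ids)], axis=1
    )
    return validate_methylation_table(meth)


@dataclass(frozen=True)
class OverexpressionConfig:
    """Inducible oncogene-overexpression experiment with empty-vector controls.

    Four cell models, each carrying either an empty vector or one oncogene
    construct, profiled at two timepoints with two replicates: 4 x 4 x 2 x 2
    = 64 samples, i.e. 16 induced samples per oncogene and 16 empty-vector
    controls. ``oncogene_tpm_factors`` multiply the focal gene's TPM in the
    induced arm; the default plants a 0.7-fold decrease for the two cell-cycle
    regulators and no consistent effect for MYC.
    """

    n_genes: int = 2000
    focal_gene: str | None = None  # default: first gene of the universe
    cell_lines: tuple[str, ...] = ("cellA", "cellB", "cellC", "cellD")
    oncogenes: tuple[str, ...] = ("CCNE1", "CDC25A", "MYC")
    timepoints: tuple[int, ...] = (48, 120)
    n_replicates: int = 2
    oncogene_tpm_factors: dict = field(
        default_factory=lambda: {"CCNE1": 0.7, "CDC25A": 0.7, "MYC": 1.0}
    )
    log_tpm_mean_range: tuple[float, float] = (1.0, 8.0)
    context_sd: float = 0.3  # per (gene, cell line, timepoint) baseline shift
    replicate_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.focal_gene is None:
            object.__setattr__(self, "focal_gene", self.gene_ids[0])
        elif self.focal_gene not in self.gene_ids:
            raise ValueError(f"focal_gene {self.focal_gene!r} not in gene universe")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


def generate_overexpression_experiment(
    config: OverexpressionConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Generate the 64-sample overexpression experiment.

    Returns the expression matrix in log2(TPM + 1) units, a design table with
    columns (sample_id, cell_line, condition, timepoint, replicate), and the
    planted truth (the per-oncogene TPM factors).
    """
    config = config or OverexpressionConfig()
    rng = child_rng(config.rng_seed, "overexpression")
    genes = config.gene_ids
    focal_idx = genes.index(config.focal_gene)
    conditions = ("Empty",) + config.oncogenes

    mu = rng.uniform(*config.log_tpm_mean_range, size=config.n_genes)
    context = {
        (cl, tp): rng.normal(0.0, config.context_sd, size=config.n_genes)
        for cl in config.cell_lines
        for tp in config.timepoints
    }

    rows = []
    columns = {}
    for cl in config.cell_lines:
        for cond in conditions:
            for tp in config.timepoints:
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{cl}_{cond}_{tp}h_r{rep}"
                    log_tpm = (
                        mu
                        + context[(cl, tp)]
                        + rng.normal(0.0, config.replicate_sd, size=config.n_genes)
                    )
                    if cond != "Empty":
                        log_tpm[focal_idx] += np.log2(
                            config.oncogene_tpm_factors.get(cond, 1.0)
                        )
                    columns[sid] = np.log2(2.0**log_tpm + 1.0)
                    rows.append((sid, cl, cond, tp, rep))
    design = pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "condition", "timepoint", "replicate"]
    )
    expr = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    truth = {
        "focal_gene": config.focal_gene,
        "oncogene_tpm_factors": dict(config.oncogene_tpm_factors),
    }
    return expr, design, truth
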