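"""Genome-wide empirical-null tests for a focal gene.

Instead of a per-gene parametric test, the screen asks how extreme one focal
gene's statistic (Spearman correlation with aneuploidy, or mutation rate per
kilobase) is relative to the same statistic computed for every other gene.
The per-gene statistics are standardized (sample sd, n-1) and the focal
gene's one-sided p comes from the normal CDF of its z-score — a one-sample
Z test against the genome-wide distribution. A pan-cancer summary takes the
per-gene median statistic across cancer types and repeats the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, TUMOR

logger = logging.getLogger("pancscreen")

__all__ = [
    "FocalNullResult",
    "spearman",
    "genomewide_association",
    "standardized_one_sided_p",
    "pancan_median_association",
    "mutation_rate_per_kb",
    "mutation_depletion_test",
    "pancan_mutation_depletion",
]


@dataclass(frozen=True)
class FocalNullResult:
    """One-sample Z test of a focal gene against the genome-wide null."""

    focal_gene: str
    z: float
    p_one_sided: float
    n_genes: int
    tail: str  # lower | upper
    empirical_quantile: float  # diagnostic: rank-based quantile of the focal value
    focal_value: float


def spearman(x, y, min_pairs: int = 3) -> float:
    """Tie-aware Spearman correlation with pairwise missing-value removal.

    Returns NaN (with a warning) when either vector is constant after
    pairing, and raises when fewer than ``min_pairs`` complete pairs remain.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < min_pairs:
        raise ValueError(f"spearman requires >= {min_pairs} paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("spearman: constant input vector; correlation undefined")
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, axis=1)


def genomewide_association(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    cancer_type: str,
    min_pairs: int = 3,
) -> pd.Series:
    """Spearman rho of every gene vs aneuploidy over one cancer's tumor arm.

    Vectorized as Pearson correlation of average ranks. Genes constant across
    the scored tumor samples get NaN.
    """
    sub = samples[
        (samples["cancer_type"] == cancer_type)
        & (samples["sample_class"] == TUMOR)
        & samples["aneuploidy_score"].notna()
        & samples["sample_id"].isin(expr.sample_ids)
    ]
    if len(sub) < min_pairs:
        raise ValueError(
            f"cancer {cancer_type!r}: fewer than {min_pairs} tumor samples with "
            "aneuploidy scores"
        )
    mat = expr.data[sub["sample_id"].tolist()].to_numpy()
    scores = sub["aneuploidy_score"].to_numpy(float)

    gene_ranks = _rank_rows(mat)
    score_ranks = sps.rankdata(scores)
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    sr = score_ranks - score_ranks.mean()
    denom = np.sqrt((gr**2).sum(axis=1) * (sr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ sr) / denom
    rho[denom == 0] = np.nan
    n_const = int(np.isnan(rho).sum())
    if n_const:
        logger.warning(
            "genomewide_association(%s): %d constant genes -> NaN", cancer_type, n_const
        )
    return pd.Series(rho, index=expr.gene_ids, name=cancer_type)


def standardized_one_sided_p(
    values: pd.Series, focal_gene: str, tail: str = "lower", min_genes: int = 30
) -> FocalNullResult:
    """One-sample Z test of the focal gene against all genes' statistics.

    z = (value_focal - mean(all)) / sd(all) with sample sd (n-1);
    p = Phi(z) for the lower tail, 1 - Phi(z) for the upper. NaN statistics
    are dropped. The rank-based empirical quantile is carried along as a
    diagnostic.
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    values = values.dropna()
    if focal_gene not in values.index:
        raise KeyError(f"focal gene {focal_gene!r} has no finite statistic")
    if len(values) < min_genes:
        raise ValueError(f"need >= {min_genes} genes in the null distribution")
    arr = values.to_numpy(float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("null distribution has zero variance")
    focal_value = float(values[focal_gene])
    z = (focal_value - arr.mean()) / sd
    p = float(sps.norm.cdf(z) if tail == "lower" else sps.norm.sf(z))
    # mid-rank empirical quantile of the focal value within the null
    less = np.sum(arr < focal_value)
    equal = np.sum(arr == focal_value)
    quantile = float((less + 0.5 * equal) / arr.size)
    return FocalNullResult(
        focal_gene=focal_gene,
        z=float(z),
        p_one_sided=min(max(p, np.nextafter(0, 1)), 1.0 - np.nextafter(0, 1) * 0),
        n_genes=int(arr.size),
        tail=tail,
        empirical_quantile=quantile,
        focal_value=focal_value,
    )


def pancan_median_association(
    tables: dict[str, pd.Series] | pd.DataFrame,
    focal_gene: str,
    tail: str = "lower",
    min_genes: int = 30,
) -> tuple[pd.Series, FocalNullResult]:
    """Median per-gene statistic across cancers, then the one-sample Z test.

    Only genes with a finite statistic in every cancer enter the median
    (keeping the null distribution comparable across genes). Returns the
    median series and the focal result.
    """
    if isinstance(tables, dict):
        if len(tables) < 2:
            raise ValueError("pan-cancer median needs >= 2 cancers")
        table = pd.DataFrame(tables)
    else:
        table = tables
        if table.shape[1] < 2:
            raise ValueError("pan-cancer median needs >= 2 cancers")
    complete = table.dropna()
    if complete.empty:
        raise ValueError("no gene has a statistic in every cancer")
    medians = complete.median(axis=1)
    return medians, standardized_one_sided_p(
        medians, focal_gene, tail=tail, min_genes=min_genes
    )


def mutation_rate_per_kb(
    mutations: pd.DataFrame,
    annotation: pd.DataFrame,
    cancer_type: str | None = None,
    effect_class: str | None = None,
) -> pd.Series:
    """Mutations per kilobase for every annotated gene.

    Counts mutation records (optionally restricted to one cancer type and/or
    one effect class) and divides by gene length in kb. Genes without
    records get rate 0. Records for genes absent from the annotation raise.
    """
    sub = mutations
    if cancer_type is not None:
        sub = sub[sub["cancer_type"] == cancer_type]
    if effect_class is not None:
        sub = sub[sub["effect_class"] == effect_class]
    known = set(annotation["gene_id"])
    unknown = set(sub["gene_id"]) - known
    if unknown:
        raise KeyError(f"mutated genes missing from annotation: {sorted(unknown)[:5]}")
    counts = sub.groupby("gene_id").size()
    lengths_kb = annotation.set_index("gene_id")["length_bp"] / 1000.0
    rates = counts.reindex(lengths_kb.index, fill_value=0) / lengths_kb
    rates.name = f"{cancer_type or 'all'}:{effect_class or 'all'}"
    return rates


def mutation_depletion_test(
    rates: pd.Series, focal_gene: str, tail: str = "lower"
) -> FocalNullResult:
    """One-sample Z test of the focal gene's mutation rate per kb."""
    return standardized_one_sided_p(rates, focal_gene, tail=tail)


def pancan_mutation_depletion(
    mutations: pd.DataFrame,
    annotation: pd.DataFrame,
    cancer_types: list[str],
    focal_gene: str,
    effect_class: str | None = None,
    tail: str = "lower",
) -> tuple[pd.Series, FocalNullResult]:
    """Per-gene median mutation rate across cancers, then the focal Z test.

    Mirrors the pan-cancer association pipeline: per-cancer rates per kb,
    per-gene median across the given cancers, standardized one-sided p.
    """
    tables = {
        c: mutation_rate_per_kb(mutations, annotation, c, effect_class)
        for c in cancer_types
    }
    return pancan_median_association(tables, focal_gene, tail=tail)
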