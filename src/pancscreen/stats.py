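"""Per-cancer two-group testing and the screen's consistency statistics.

The screen calls a gene "down" or "up" per cancer from a two-sided Wilcoxon
rank-sum test on log-normalized expression (tumor vs unmatched healthy solid
tissue), then asks whether one family member's direction calls are more
consistent across cancers than a trinary null allows (binomial test). The
same Wilcoxon machinery backs regulator-stratified comparisons, the
oncogene-overexpression effect test, and the promoter methylation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    AnalysisConfig,
    ExpressionMatrix,
    HEALTHY,
    TUMOR,
)
from .io import filter_cancers_by_arm_size

logger = logging.getLogger("pancscreen")

__all__ = [
    "DiffExpResult",
    "wilcoxon_rank_sum",
    "diffexp_per_cancer",
    "family_direction_table",
    "family_consistency_binomial",
    "stratify_by_regulators",
    "compare_strata_expression",
    "oncogene_effect_test",
    "promoter_methylation_test",
    "significance_marker",
]

PANCAN = "PANCAN"


@dataclass(frozen=True)
class DiffExpResult:
    """One two-group comparison for one gene in one cancer type."""

    cancer_type: str
    gene_id: str
    statistic: float
    p_two_sided: float
    direction: str  # down | up | ns
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def significance_marker(p: float) -> str:
    """Conventional star annotation for a nominal p-value."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when n + m <= 16 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections. Returns the
    U statistic of ``x`` and the two-sided p-value in (0, 1].
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        logger.warning("wilcoxon_rank_sum: all values identical; p = 1")
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 16 and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p


def _one_comparison(
    cancer: str,
    gene_id: str,
    tumor_vals: np.ndarray,
    healthy_vals: np.ndarray,
    alpha: float,
) -> DiffExpResult:
    stat, p = wilcoxon_rank_sum(tumor_vals, healthy_vals)
    med_t, med_h = float(np.median(tumor_vals)), float(np.median(healthy_vals))
    if p < alpha:
        direction = "down" if med_t < med_h else "up"
        if med_t == med_h:
            direction = "ns"  # significant rank shift but equal medians: no call
    else:
        direction = "ns"
    return DiffExpResult(
        cancer_type=cancer,
        gene_id=gene_id,
        statistic=stat,
        p_two_sided=p,
        direction=direction,
        median_a=med_t,
        median_b=med_h,
        n_a=int(tumor_vals.size),
        n_b=int(healthy_vals.size),
    )


def diffexp_per_cancer(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    gene_id: str,
    alpha: float = 0.05,
    min_samples_per_arm: int = 20,
) -> list[DiffExpResult]:
    """Tumor-vs-healthy Wilcoxon per retained cancer type, plus a PANCAN row.

    Cancers failing the arm-size filter are excluded; the PANCAN row pools
    tumor and healthy samples across all retained cancers. Direction is the
    sign of median(tumor) - median(healthy) when p < alpha, else "ns".
    """
    gene = expr.gene(gene_id)
    retained = filter_cancers_by_arm_size(expr, samples, min_samples_per_arm)
    present = samples[samples["sample_id"].isin(expr.sample_ids)]
    results: list[DiffExpResult] = []
    pooled_t, pooled_h = [], []
    for cancer in retained:
        sub = present[present["cancer_type"] == cancer]
        t_ids = sub.loc[sub["sample_class"] == TUMOR, "sample_id"]
        h_ids = sub.loc[sub["sample_class"] == HEALTHY, "sample_id"]
        t_vals = gene[t_ids].to_numpy()
        h_vals = gene[h_ids].to_numpy()
        results.append(_one_comparison(cancer, gene_id, t_vals, h_vals, alpha))
        pooled_t.append(t_vals)
        pooled_h.append(h_vals)
    if pooled_t:
        results.append(
            _one_comparison(
                PANCAN, gene_id, np.concatenate(pooled_t), np.concatenate(pooled_h), alpha
            )
        )
    return results


def family_direction_table(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    family_gene_ids: list[str],
    alpha: float = 0.05,
    min_samples_per_arm: int = 20,
) -> pd.DataFrame:
    """Direction calls (down/up/ns) for every family gene x retained cancer.

    Rows are genes, columns the retained cancer types (PANCAN excluded).
    """
    table: dict[str, dict[str, str]] = {}
    for gene_id in family_gene_ids:
        rows = diffexp_per_cancer(expr, samples, gene_id, alpha, min_samples_per_arm)
        table[gene_id] = {
            r.cancer_type: r.direction for r in rows if r.cancer_type != PANCAN
        }
    return pd.DataFrame(table).T


def family_consistency_binomial(
    directions, null_p: float = 1.0 / 3.0, call: str = "down"
) -> tuple[float, int, int]:
    """One-sided binomial tail for consistency of one gene's direction calls.

    ``directions`` is the gene's per-cancer calls (down/up/ns). With k the
    number of cancers called ``call`` out of n cancers, returns
    P(K >= k | n, null_p) together with (k, n). The default null_p = 1/3
    treats the three calls as equally likely under no consistent effect.
    """
    directions = list(directions)
    n = len(directions)
    if n == 0:
        raise ValueError("no direction calls given")
    bad = set(directions) - {"down", "up", "ns"}
    if bad:
        raise ValueError(f"invalid direction values: {sorted(bad)}")
    k = sum(d == call for d in directions)
    p = float(sps.binom.sf(k - 1, n, null_p))  # P(K >= k)
    return min(p, 1.0), k, n


def stratify_by_regulators(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    regulator_gene_ids: list[str],
    decile_fraction: float = 0.10,
) -> pd.DataFrame:
    """Label tumor samples regulator_high / regulator_low / other, per cancer.

    Within each cancer type's tumor arm, regulator_high is the union over
    regulators of each regulator's top ``decile_fraction`` of samples;
    regulator_low is the intersection of the bottom fractions of ALL
    regulators. Quantile boundaries use the inclusive nearest-rank rule
    (k = ceil(fraction * n); ties at the boundary value are included). A
    cancer where the two strata would overlap, or with fewer tumor samples
    than 1/decile_fraction, is skipped with a warning.

    Returns a DataFrame with columns (sample_id, cancer_type, stratum).
    """
    if not regulator_gene_ids:
        raise ValueError("need at least one regulator gene")
    reg_expr = {g: expr.gene(g) for g in regulator_gene_ids}
    present = samples[samples["sample_id"].isin(expr.sample_ids)]
    tumors = present[present["sample_class"] == TUMOR]
    out_rows = []
    for cancer in tumors["cancer_type"].drop_duplicates():
        ids = tumors.loc[tumors["cancer_type"] == cancer, "sample_id"].tolist()
        n = len(ids)
        if n < int(np.ceil(1.0 / decile_fraction)):
            logger.warning(
                "stratify_by_regulators: cancer %s skipped (%d tumor samples)", cancer, n
            )
            continue
        k = int(np.ceil(decile_fraction * n))
        high: set[str] = set()
        low: set[str] | None = None
        for g in regulator_gene_ids:
            vals = reg_expr[g][ids].to_numpy()
            order = np.sort(vals)
            hi_thresh = order[-k]  # k-th largest
            lo_thresh = order[k - 1]  # k-th smallest
            high |= {s for s, v in zip(ids, vals) if v >= hi_thresh}
            lows = {s for s, v in zip(ids, vals) if v <= lo_thresh}
            low = lows if low is None else (low & lows)
        low = low or set()
        if high & low:
            logger.warning(
                "stratify_by_regulators: cancer %s skipped (high/low overlap)", cancer
            )
            continue
        for s in ids:
            stratum = (
                "regulator_high" if s in high else "regulator_low" if s in low else "other"
            )
            out_rows.append((s, cancer, stratum))
    return pd.DataFrame(out_rows, columns=["sample_id", "cancer_type", "stratum"])


def compare_strata_expression(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    strata: pd.DataFrame,
    target_gene: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon of target expression: healthy vs each tumor stratum, per cancer.

    Returns one row per (cancer, stratum in {regulator_high, regulator_low})
    plus PANCAN rows pooling per-cancer labels. An empty stratum yields a row
    with ``testable = False``.
    """
    gene = expr.gene(target_gene)
    present = samples[samples["sample_id"].isin(expr.sample_ids)]
    healthy = present[present["sample_class"] == HEALTHY]
    rows = []
    pooled: dict[str, list[np.ndarray]] = {"regulator_high": [], "regulator_low": []}
    pooled_h: list[np.ndarray] = []
    cancers = strata["cancer_type"].drop_duplicates().tolist()
    for cancer in cancers:
        h_vals = gene[healthy.loc[healthy["cancer_type"] == cancer, "sample_id"]].to_numpy()
        pooled_h.append(h_vals)
        for stratum in ("regulator_high", "regulator_low"):
            ids = strata.loc[
                (strata["cancer_type"] == cancer) & (strata["stratum"] == stratum),
                "sample_id",
            ]
            s_vals = gene[ids].to_numpy()
            pooled[stratum].append(s_vals)
            rows.append(_stratum_row(cancer, stratum, target_gene, s_vals, h_vals, alpha))
    if cancers:
        h_all = np.concatenate(pooled_h)
        for stratum in ("regulator_high", "regulator_low"):
            s_all = (
                np.concatenate(pooled[stratum]) if pooled[stratum] else np.array([])
            )
            rows.append(_stratum_row(PANCAN, stratum, target_gene, s_all, h_all, alpha))
    return pd.DataFrame(rows)


def _stratum_row(cancer, stratum, gene_id, s_vals, h_vals, alpha) -> dict:
    if s_vals.size == 0 or h_vals.size == 0:
        return {
            "cancer_type": cancer,
            "stratum": stratum,
            "gene_id": gene_id,
            "statistic": np.nan,
            "p_two_sided": np.nan,
            "direction": "untestable",
            "n_stratum": int(s_vals.size),
            "n_healthy": int(h_vals.size),
            "testable": False,
        }
    res = _one_comparison(cancer, gene_id, s_vals, h_vals, alpha)
    return {
        "cancer_type": cancer,
        "stratum": stratum,
        "gene_id": gene_id,
        "statistic": res.statistic,
        "p_two_sided": res.p_two_sided,
        "direction": res.direction,
        "n_stratum": res.n_a,
        "n_healthy": res.n_b,
        "testable": True,
    }


def oncogene_effect_test(
    oe_expr: ExpressionMatrix,
    design: pd.DataFrame,
    target_gene: str,
) -> dict[str, dict]:
    """Control-normalized effect of each oncogene on the target gene.

    For every sample, the normalized value is its log2(TPM + 1) minus the
    mean log2(TPM + 1) of the matched empty-vector arm (same cell line and
    timepoint). Each oncogene's induced samples are then compared against the
    empty-vector samples with a Wilcoxon rank-sum test.

    Returns {oncogene: {"normalized": Series, "control_normalized": Series,
    "statistic": U, "p": p}}.
    """
    gene = oe_expr.gene(target_gene)
    design = design.set_index("sample_id", drop=False)
    control_means: dict[tuple, float] = {}
    empty = design[design["condition"] == "Empty"]
    for (cl, tp), grp in empty.groupby(["cell_line", "timepoint"]):
        control_means[(cl, tp)] = float(gene[grp["sample_id"]].mean())

    def normalize(rows: pd.DataFrame) -> pd.Series:
        vals = {}
        for sid, row in rows.iterrows():
            key = (row["cell_line"], row["timepoint"])
            if key not in control_means:
                raise ValueError(f"no Empty control arm for cell line/timepoint {key}")
            vals[sid] = float(gene[sid]) - control_means[key]
        return pd.Series(vals)

    control_norm = normalize(empty)
    out: dict[str, dict] = {}
    for oncogene in design.loc[design["condition"] != "Empty", "condition"].unique():
        treated = design[design["condition"] == oncogene]
        treated_norm = normalize(treated)
        stat, p = wilcoxon_rank_sum(treated_norm.to_numpy(), control_norm.to_numpy())
        out[oncogene] = {
            "normalized": treated_norm,
            "control_normalized": control_norm,
            "statistic": stat,
            "p": p,
        }
    return out


def promoter_window(tss: int, strand: str, window_bp: int) -> tuple[int, int]:
    """Half-open [start, end) window of ``window_bp`` upstream of the TSS."""
    if strand == "+":
        return max(tss - window_bp, 0), tss
    return tss + 1, tss + window_bp + 1


def promoter_methylation_test(
    meth: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    gene_id: str,
    window_bp: int = 1500,
    alpha: float = 0.05,
) -> tuple[pd.Series | None, pd.DataFrame]:
    """Tumor-vs-healthy test of median promoter methylation, per cancer.

    The promoter window is the ``window_bp`` bases upstream of the gene's
    TSS (strand-aware, half-open). The per-sample statistic is the median
    beta over probes whose position falls in the window (chromosome-matched).
    Returns (per-sample medians, per-cancer result table); medians is None
    and the table empty when no probe falls in the window.
    """
    ann = annotation.set_index("gene_id")
    if gene_id not in ann.index:
        raise KeyError(f"gene {gene_id!r} not in annotation")
    tss, strand, chrom = (
        int(ann.loc[gene_id, "tss"]),
        ann.loc[gene_id, "strand"],
        ann.loc[gene_id, "chrom"],
    )
    start, end = promoter_window(tss, strand, window_bp)
    in_window = meth[
        (meth["chrom"] == chrom) & (meth["position"] >= start) & (meth["position"] < end)
    ]
    if in_window.empty:
        logger.warning(
            "promoter_methylation_test: no probes in window for %s; untestable", gene_id
        )
        return None, pd.DataFrame(
            columns=["cancer_type", "statistic", "p_two_sided", "direction", "testable"]
        )
    beta_cols = [c for c in meth.columns if c not in ("probe_id", "chrom", "position")]
    medians = in_window[beta_cols].median(axis=0)

    present = samples[samples["sample_id"].isin(beta_cols)]
    rows = []
    for cancer in present["cancer_type"].drop_duplicates():
        sub = present[present["cancer_type"] == cancer]
        t_vals = medians[sub.loc[sub["sample_class"] == TUMOR, "sample_id"]].to_numpy()
        h_vals = medians[sub.loc[sub["sample_class"] == HEALTHY, "sample_id"]].to_numpy()
        if t_vals.size == 0 or h_vals.size == 0:
            rows.append(
                {
                    "cancer_type": cancer,
                    "statistic": np.nan,
                    "p_two_sided": np.nan,
                    "direction": "untestable",
                    "testable": False,
                }
            )
            continue
        res = _one_comparison(cancer, gene_id, t_vals, h_vals, alpha)
        rows.append(
            {
                "cancer_type": cancer,
                "statistic": res.statistic,
                "p_two_sided": res.p_two_sided,
                "direction": res.direction,
                "testable": True,
            }
        )
    return medians, pd.DataFrame(rows)
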