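"""Differential co-expression of a focal gene between tumor and healthy tissue.

A co-expression signature is the vector of Spearman correlations between the
focal gene and every other gene across the samples of one class (tumor or
healthy), pooled over cancer types. Running the same gene-set collection
through preranked GSEA on both signatures with paired permutation seeds
yields a delta NES (tumor minus healthy) per set — the measure of
tumor-rewired co-expression — plus the "qualifies" filter (BH FDR < threshold
in at least one class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GeneSetCollection
from .gsea import RankedSignature, rank_signature, run_collection

logger = logging.getLogger("pancscreen")

__all__ = [
    "DeltaNESRecord",
    "coexpression_signature",
    "delta_nes_analysis",
    "intersect_enriched_targets",
    "rank_targets_by_coexpression",
]


@dataclass(frozen=True)
class DeltaNESRecord:
    set_name: str
    nes_tumor: float
    nes_healthy: float
    delta_nes: float
    fdr_tumor: float
    fdr_healthy: float
    qualifies: bool


def coexpression_signature(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    focal_gene: str,
    sample_class: str,
    min_samples: int = 3,
) -> RankedSignature:
    """Ranked Spearman co-expression signature of the focal gene in one class.

    Correlates the focal gene with every other gene across all samples of the
    given class (pooled over cancer types), excluding the focal gene itself.
    Vectorized as Pearson on average ranks. Genes constant across the class
    samples get rho 0 (no rank information) with a logged count.
    """
    ids = samples.loc[
        (samples["sample_class"] == sample_class)
        & samples["sample_id"].isin(expr.sample_ids),
        "sample_id",
    ].tolist()
    if len(ids) < min_samples:
        raise ValueError(f"fewer than {min_samples} samples of class {sample_class!r}")
    mat = expr.data[ids]
    focal = mat.loc[focal_gene].to_numpy()
    if np.unique(focal).size == 1:
        raise ValueError("focal gene is constant across the selected samples")
    others = mat.drop(index=focal_gene)

    gene_ranks = sps.rankdata(others.to_numpy(), axis=1)
    focal_ranks = sps.rankdata(focal)
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    fr = focal_ranks - focal_ranks.mean()
    denom = np.sqrt((gr**2).sum(axis=1) * (fr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ fr) / denom
    n_const = int((denom == 0).sum())
    if n_const:
        logger.warning("coexpression_signature: %d constant genes -> rho 0", n_const)
    rho[denom == 0] = 0.0
    return rank_signature(pd.Series(rho, index=others.index))


def delta_nes_analysis(
    sig_tumor: RankedSignature,
    sig_healthy: RankedSignature,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    min_size: int = 5,
    max_size: int = 5000,
) -> list[DeltaNESRecord]:
    """Delta NES (tumor minus healthy) for every set tested in both classes.

    Both signatures must cover the same gene universe. The same per-set child
    seeds are used for both runs, so comparing a signature against itself
    yields delta NES exactly zero. NES is computed in both classes regardless
    of significance; the ``qualifies`` flag records whether the set reached
    BH FDR < ``fdr_threshold`` in at least one class. Records are sorted by
    |delta NES| descending.
    """
    if set(sig_tumor.gene_ids) != set(sig_healthy.gene_ids):
        raise ValueError("tumor and healthy signatures cover different gene universes")
    kwargs = dict(
        n_permutations=n_permutations,
        seed=seed,
        min_size=min_size,
        max_size=max_size,
    )
    res_t = run_collection(sig_tumor, collection, **kwargs).set_index("set_name")
    res_h = run_collection(sig_healthy, collection, **kwargs).set_index("set_name")
    common = [n for n in res_t.index if n in res_h.index]
    records = []
    for name in common:
        t, h = res_t.loc[name], res_h.loc[name]
        if not (t["testable"] and h["testable"]):
            continue
        delta = float(t["nes"] - h["nes"])
        qualifies = bool(min(t["fdr_bh"], h["fdr_bh"]) < fdr_threshold)
        records.append(
            DeltaNESRecord(
                set_name=name,
                nes_tumor=float(t["nes"]),
                nes_healthy=float(h["nes"]),
                delta_nes=delta,
                fdr_tumor=float(t["fdr_bh"]),
                fdr_healthy=float(h["fdr_bh"]),
                qualifies=qualifies,
            )
        )
    records.sort(key=lambda r: (-abs(r.delta_nes), r.set_name))
    return records


def intersect_enriched_targets(
    qualifying_sets: list[str], collection: GeneSetCollection
) -> tuple[list[str], dict[tuple[str, str], int]]:
    """Exact intersection of qualifying sets' members plus pairwise overlaps.

    Returns (sorted full-intersection gene list, {(setA, setB): overlap size}
    for every unordered pair).
    """
    if len(qualifying_sets) < 2:
        raise ValueError("need at least two qualifying sets to intersect")
    members = {name: set(collection[name]) for name in qualifying_sets}
    full = set.intersection(*members.values())
    pairwise: dict[tuple[str, str], int] = {}
    names = sorted(qualifying_sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = len(members[a] & members[b])
    return sorted(full), pairwise


def rank_targets_by_coexpression(
    sig_tumor: RankedSignature,
    target_genes,
    top_k: int | None = None,
    by_absolute: bool = True,
) -> pd.Series:
    """Targets ordered by their tumor co-expression with the focal gene.

    Default ordering is by |rho| descending (signed ordering available);
    ties broken by gene id. ``top_k`` slices the head; raises on an empty
    target list, and on targets outside the signature universe.
    """
    targets = list(target_genes)
    if not targets:
        raise ValueError("empty target gene list")
    scores = sig_tumor.to_series()
    missing = [g for g in targets if g not in scores.index]
    if missing:
        raise KeyError(f"targets not in signature: {missing[:5]}")
    sub = scores[targets]
    key = sub.abs() if by_absolute else sub
    order = (
        pd.DataFrame({"key": key, "gene": sub.index})
        .sort_values(["key", "gene"], ascending=[False, True], kind="mergesort")["gene"]
        .tolist()
    )
    ranked = sub[order]
    if top_k is not None:
        ranked = ranked.iloc[: max(top_k, 0)]
    return ranked
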