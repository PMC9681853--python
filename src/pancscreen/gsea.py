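"""From-scratch preranked gene-set enrichment analysis.

Classic weighted Kolmogorov-Smirnov running sum with weight exponent 1:
walking down the ranked list, a gene-set member ("hit") advances the sum by
its |score| / sum of member |scores|, a non-member ("miss") retreats it by
1 / (N - n_set). The enrichment score (ES) is the signed maximal deviation
from zero. The null is gene-permutation: ES of random same-size sets drawn
from the signature. NES divides ES by the mean |null ES| of matching sign,
and the permutation p-value is computed within the same-sign null draws with
the standard +1 correction. BH FDR is applied across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .containers import GeneSetCollection

logger = logging.getLogger("pancscreen")

__all__ = [
    "RankedSignature",
    "EnrichmentResult",
    "rank_signature",
    "enrichment_score",
    "gsea_permutation_test",
    "benjamini_hochberg",
    "run_collection",
]


@dataclass(frozen=True)
class RankedSignature:
    """Genes ordered by descending score; ties broken by gene id."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray  # aligned with gene_ids, descending
    tie_policy: str = "lexicographic gene id"

    def __post_init__(self):
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in signature")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("signature scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.gene_ids))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr_bh: float
    set_size_used: int
    testable: bool = True


def rank_signature(scores, descending: bool = True) -> RankedSignature:
    """Build a ranked signature from a gene -> score mapping or Series.

    Stable ordering: by score (descending by default), ties broken by
    lexicographic gene id, so the result is invariant to input order.
    """
    series = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if series.empty:
        raise ValueError("empty signature")
    if series.isna().any():
        raise ValueError("NaN scores in signature")
    frame = series.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(
        ["score", "gene"], ascending=[not descending, True], kind="mergesort"
    )
    sig_scores = frame["score"].to_numpy(float)
    if not descending:
        # internal representation is always descending
        frame = frame.iloc[::-1]
        sig_scores = frame["score"].to_numpy(float)
    return RankedSignature(tuple(frame["gene"]), sig_scores)


def _es_from_positions(
    positions: np.ndarray, abs_scores: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed ES for each row of member positions (sorted ascending per row).

    The running sum is piecewise linear, so its extrema occur immediately
    after a hit (maximum candidates) or immediately before a hit (minimum
    candidates); only member positions are needed.
    """
    if positions.ndim == 1:
        positions = positions[None, :]
    n_perm, n_set = positions.shape
    if n_set >= n_total:
        raise ValueError("gene set covers the whole signature (no misses)")
    w = abs_scores[positions]
    totals = w.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("gene set has zero total |score|; ES undefined")
    cum = np.cumsum(w, axis=1) / totals
    miss = 1.0 / (n_total - n_set)
    idx = np.arange(n_set)
    misses_before = positions - idx  # misses seen before each hit
    after_hit = cum - miss * misses_before
    before_hit = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1
    ) - miss * misses_before
    peak = after_hit.max(axis=1)
    trough = before_hit.min(axis=1)
    # magnitude ties (to float tolerance) resolve to the positive deviation
    return np.where(peak + trough >= -1e-9, peak, trough)


def enrichment_score(
    sig: RankedSignature, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set plus the full running sum (for inspection/plots).

    Only set members present in the signature count; raises when the
    intersection is empty or the set covers every gene. If the largest
    positive and negative deviations tie in magnitude exactly, the positive
    one is returned.
    """
    index = sig.index
    positions = np.array(sorted(index[g] for g in gene_set if g in index), dtype=int)
    if positions.size == 0:
        raise ValueError("gene set has no members in the signature")
    n = len(sig)
    if positions.size >= n:
        raise ValueError("gene set covers the whole signature (no misses)")
    abs_scores = np.abs(sig.scores) ** weight_exponent
    es = float(_es_from_positions(positions, abs_scores, n)[0])

    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    steps = np.where(hit, abs_scores / abs_scores[positions].sum(), -1.0 / (n - positions.size))
    running = np.cumsum(steps)
    return es, running


def gsea_permutation_test(
    sig: RankedSignature,
    gene_set,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Gene-permutation null for one set: NES and permutation p-value.

    Null ES come from random same-size gene sets drawn from the signature.
    NES = ES / mean(|null ES| of matching sign); p = (1 + #{same-sign null at
    least as extreme}) / (1 + #{same-sign null}). Deterministic given seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    index = sig.index
    members = sorted(g for g in gene_set if g in index)
    if not members:
        raise ValueError("gene set has no members in the signature")
    positions = np.array([index[g] for g in members], dtype=int)
    positions.sort()
    n = len(sig)
    abs_scores = np.abs(sig.scores) ** weight_exponent
    es = float(_es_from_positions(positions, abs_scores, n)[0])

    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n))
    null_pos = np.argpartition(keys, positions.size, axis=1)[:, : positions.size]
    null_pos.sort(axis=1)
    null_es = _es_from_positions(null_pos, abs_scores, n)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("gsea_permutation_test: no same-sign null draws; untestable")
        return EnrichmentResult(
            set_name="", es=es, nes=float("nan"), p_perm=float("nan"),
            fdr_bh=float("nan"), set_size_used=positions.size, testable=False,
        )
    null_same = null_es[same_sign]
    nes = es / float(np.abs(null_same).mean())
    p = (1 + int((np.abs(null_same) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(
        set_name="",
        es=es,
        nes=float(nes),
        p_perm=float(p),
        fdr_bh=float("nan"),
        set_size_used=int(positions.size),
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjustment with enforced monotonicity, capped at 1."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(pvalues, float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_collection(
    sig: RankedSignature,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 5000,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of every set in a collection, with BH FDR across sets.

    Each set gets its own child seed derived from (seed, set name), so the
    same seed pairing can be reused on a second signature for exactly paired
    nulls. Sets with fewer than ``min_size`` (or more than ``max_size``)
    members present in the signature are skipped and reported in the log.
    """
    index = sig.index
    rows = []
    skipped = []
    for name in collection:
        present = [g for g in collection[name] if g in index]
        if not (min_size <= len(present) <= max_size):
            skipped.append(name)
            continue
        res = gsea_permutation_test(
            sig,
            present,
            n_permutations=n_permutations,
            seed=_set_seed(seed, name),
            weight_exponent=weight_exponent,
        )
        rows.append(
            {
                "set_name": name,
                "es": res.es,
                "nes": res.nes,
                "p_perm": res.p_perm,
                "set_size_used": res.set_size_used,
                "testable": res.testable,
            }
        )
    if skipped:
        logger.warning("run_collection: %d sets outside size bounds skipped", len(skipped))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "es", "nes", "p_perm", "set_size_used", "testable"],
    )
    if out.empty:
        logger.warning("run_collection: no testable sets")
        out["fdr_bh"] = pd.Series(dtype=float)
        return out
    fdr = np.full(len(out), np.nan)
    mask = out["testable"].to_numpy()
    if mask.any():
        fdr[mask] = benjamini_hochberg(out.loc[mask, "p_perm"].to_numpy())
    out["fdr_bh"] = fdr
    return out


def _set_seed(seed: int, set_name: str) -> int:
    from ._rng import child_seed

    return child_seed(seed, "gsea", set_name)
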