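"""Shared domain containers and table validators.

The pipeline works on plain pandas objects with documented column contracts;
the two containers that carry non-trivial invariants (the expression matrix
and gene-set collections) are thin validated wrappers.

Column contracts
----------------
sample table : columns ``sample_id``, ``cancer_type``, ``sample_class``
    (``healthy_solid`` | ``primary_tumor``) and ``aneuploidy_score``
    (non-negative for tumors, NaN for healthy samples).
gene annotation : columns ``gene_id``, ``length_bp`` (>0), ``chrom``,
    ``tss`` (0-based), ``strand`` (``+`` | ``-``).
mutation table : one row per somatic mutation event with columns
    ``gene_id``, ``sample_id``, ``cancer_type``, ``effect_class``.
methylation table : probe metadata columns ``probe_id``, ``chrom``,
    ``position`` (0-based) followed by one beta column per sample in [0, 1].
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pancscreen")

HEALTHY = "healthy_solid"
TUMOR = "primary_tumor"
SAMPLE_CLASSES = (HEALTHY, TUMOR)


class FormatError(ValueError):
    """A tabular input violates its format contract."""


class ExpressionMatrix:
    """Genes x samples matrix of log-normalized expression.

    Values are log2(count + 1) units (or any pre-normalized log scale passed
    through unchanged). Invariants: unique gene and sample ids, no infinities,
    no negative values. NaN marks a missing measurement; downstream stages
    drop missing (gene, sample) pairs pairwise.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isinf(values).any():
            raise FormatError("expression matrix contains infinite values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            logger.warning("expression matrix has %d missing cells", n_missing)
        self.data = data.astype(float).rename_axis(index=None, columns=None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class GeneSetCollection(Mapping):
    """Mapping of set name -> frozenset of member gene ids.

    Member sets are non-empty and de-duplicated; an optional description is
    kept per set (GMT column 2).
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        clean: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            members = list(members)
            unique = frozenset(members)
            if not unique:
                raise FormatError(f"gene set {name!r} is empty")
            if len(unique) < len(members):
                logger.warning(
                    "gene set %s: %d duplicate members removed",
                    name,
                    len(members) - len(unique),
                )
            clean[name] = unique
        self._sets = clean
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across the statistical stages.

    alpha : per-test significance level for direction calls.
    min_samples_per_arm : cohort inclusion rule — a cancer type is retained
        only if both its healthy and tumor arms have at least this many
        samples (default 20).
    fdr_threshold : BH threshold used for the "qualifies" flag in the
        delta-NES analysis.
    decile_fraction : fraction defining the regulator-high/low strata.
    promoter_window_bp : width of the promoter window upstream of the TSS
        used by the methylation test.
    n_permutations : gene-permutation count for the GSEA null.
    binomial_null_p : null probability that a single cancer's direction call
        equals "down" in the family-consistency test (1/3 = down/up/ns
        equally likely).
    """

    alpha: float = 0.05
    min_samples_per_arm: int = 20
    fdr_threshold: float = 0.05
    decile_fraction: float = 0.10
    promoter_window_bp: int = 1500
    n_permutations: int = 1000
    binomial_null_p: float = 1.0 / 3.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_samples_per_arm < 1:
            raise ValueError("min_samples_per_arm must be >= 1")
        if not 0 < self.decile_fraction < 0.5:
            raise ValueError("decile_fraction must lie in (0, 0.5)")
        if not 0 < self.binomial_null_p < 1:
            raise ValueError("binomial_null_p must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "cancer_type", "sample_class"}
    missing = required - set(samples.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample table")
    bad = ~samples["sample_class"].isin(SAMPLE_CLASSES)
    if bad.any():
        raise FormatError(
            f"invalid sample_class values: {samples.loc[bad, 'sample_class'].unique().tolist()}"
        )
    if samples["cancer_type"].isna().any() or (samples["cancer_type"] == "").any():
        raise FormatError("empty cancer_type in sample table")
    if "aneuploidy_score" in samples.columns:
        scores = samples["aneuploidy_score"]
        if (scores.dropna() < 0).any():
            raise FormatError("negative aneuploidy scores")
        healthy_scored = scores.notna() & (samples["sample_class"] == HEALTHY)
        if healthy_scored.any():
            raise FormatError("aneuploidy_score present for healthy samples")
    return samples


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "length_bp", "chrom", "tss", "strand"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    if (ann["length_bp"] <= 0).any():
        raise FormatError("gene lengths must be positive")
    if (ann["tss"] < 0).any():
        raise FormatError("TSS coordinates must be non-negative (0-based)")
    if (~ann["strand"].isin(["+", "-"])).any():
        raise FormatError("strand must be '+' or '-'")
    return ann


def validate_mutation_table(mut: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "sample_id", "cancer_type", "effect_class"}
    missing = required - set(mut.columns)
    if missing:
        raise FormatError(f"mutation table missing columns: {sorted(missing)}")
    return mut


def validate_methylation_table(meth: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "chrom", "position"}
    missing = required - set(meth.columns)
    if missing:
        raise FormatError(f"methylation table missing columns: {sorted(missing)}")
    if meth["probe_id"].duplicated().any():
        raise FormatError("duplicate probe ids")
    if (meth["position"] < 0).any():
        raise FormatError("probe positions must be non-negative")
    beta_cols = [c for c in meth.columns if c not in required]
    if beta_cols:
        betas = meth[beta_cols].to_numpy(float)
        finite = betas[~np.isnan(betas)]
        if ((finite < 0) | (finite > 1)).any():
            raise FormatError("beta values must lie in [0, 1]")
    return meth


def beta_columns(meth: pd.DataFrame) -> list[str]:
    """Sample (beta) columns of a methylation table."""
    return [c for c in meth.columns if c not in ("probe_id", "chrom", "position")]
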