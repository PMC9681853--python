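"""Readers and writers for the tabular formats the pipeline touches.

Everything is plain TSV with a header row, except gene sets (GMT) and
methylation probe coordinates (BED, 0-based half-open). Floats are written
with pandas' shortest-repr formatting, so write -> read -> write is
byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AnalysisConfig,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    HEALTHY,
    TUMOR,
    validate_gene_annotation,
    validate_methylation_table,
    validate_mutation_table,
    validate_sample_table,
)

logger = logging.getLogger("pancscreen")

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "log_normalize",
    "read_sample_tsv",
    "write_sample_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_mutation_tsv",
    "write_mutation_tsv",
    "read_methylation_tables",
    "write_methylation_tables",
    "read_gmt",
    "write_gmt",
    "filter_cancers_by_arm_size",
    "write_run_manifest",
]


def _read_tsv(path) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write -> read exact for float64
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric cells in column(s) {non_numeric[:5]}")
    return ExpressionMatrix(df)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.data.rename_axis("gene_id").to_csv(path, sep="\t")


def log_normalize(raw, pseudocount: float = 1.0):
    """log2(raw + pseudocount) transform of non-negative counts/TPMs.

    Accepts an array, Series or DataFrame and preserves the container type.
    Raises on negative input. With the default pseudocount, 0 maps to 0.
    """
    values = raw.to_numpy() if hasattr(raw, "to_numpy") else np.asarray(raw, float)
    if np.nanmin(values) < 0:
        raise ValueError("log_normalize requires non-negative input")
    out = np.log2(values + pseudocount)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=raw.name)
    return out


def read_sample_tsv(path) -> pd.DataFrame:
    return validate_sample_table(_read_tsv(path))


def write_sample_tsv(samples: pd.DataFrame, path) -> None:
    validate_sample_table(samples).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return validate_gene_annotation(_read_tsv(path))


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    validate_gene_annotation(ann).to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path) -> pd.DataFrame:
    return validate_mutation_table(_read_tsv(path))


def write_mutation_tsv(mut: pd.DataFrame, path) -> None:
    validate_mutation_table(mut).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated set name, description, members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{i}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_methylation_tables(bed_path, beta_path) -> pd.DataFrame:
    """Assemble a methylation table from probe BED and per-sample beta TSV.

    BED columns: chrom, start, end, probe_id (0-based half-open); the probe
    position is the BED start. The beta TSV has probe ids in its first
    column and one column per sample.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start", "end", "probe_id"]
    )
    betas = pd.read_csv(beta_path, sep="\t", index_col=0, float_precision="round_trip")
    meth = bed.rename(columns={"start": "position"})[["probe_id", "chrom", "position"]]
    meth = meth.join(betas, on="probe_id")
    missing = meth[betas.columns].isna().all(axis=1)
    if missing.any():
        raise FormatError(
            f"probes without beta values: {meth.loc[missing, 'probe_id'].tolist()[:5]}"
        )
    return validate_methylation_table(meth)


def write_methylation_tables(meth: pd.DataFrame, bed_path, beta_path) -> None:
    validate_methylation_table(meth)
    bed = pd.DataFrame(
        {
            "chrom": meth["chrom"],
            "start": meth["position"],
            "end": meth["position"] + 1,
            "probe_id": meth["probe_id"],
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    beta_cols = [c for c in meth.columns if c not in ("probe_id", "chrom", "position")]
    meth.set_index("probe_id")[beta_cols].to_csv(beta_path, sep="\t")


def filter_cancers_by_arm_size(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    min_samples_per_arm: int = 20,
) -> list[str]:
    """Cancer types with >= min samples in BOTH the healthy and tumor arm.

    Only samples that are actually columns of the expression matrix count.
    Order of the returned list follows first appearance in the sample table.
    """
    present = samples[samples["sample_id"].isin(expr.sample_ids)]
    retained: list[str] = []
    for cancer in present["cancer_type"].drop_duplicates():
        sub = present[present["cancer_type"] == cancer]
        n_healthy = int((sub["sample_class"] == HEALTHY).sum())
        n_tumor = int((sub["sample_class"] == TUMOR).sum())
        if n_healthy >= min_samples_per_arm and n_tumor >= min_samples_per_arm:
            retained.append(cancer)
    return retained


def write_run_manifest(path, config: AnalysisConfig, seed: int, extra: dict | None = None) -> None:
    """Write a JSON manifest recording seed, config hash and package version."""
    from . import __version__

    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
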