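import numpy as np
import pandas as pd
import pytest

import pancscreen as ps


@pytest.fixture(scope="session")
def small_cohort() -> ps.SyntheticCohort:
    """A reduced cohort for structural tests (fast to generate)."""
    cfg = ps.CohortConfig(
        n_cancers=3,
        n_healthy=10,
        n_tumor=10,
        n_genes=200,
        set_size_range=(8, 30),
        n_gene_sets=6,
        rng_seed=42,
    )
    return ps.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort() -> ps.SyntheticCohort:
    """One full-size cohort (13 cancers, 25+25, 2000 genes), seed 1."""
    return ps.generate_cohort(ps.CohortConfig(rng_seed=1))


def expression_from_dict(values: dict[str, dict[str, float]]) -> ps.ExpressionMatrix:
    """Build a tiny expression matrix from {gene: {sample: value}}."""
    return ps.ExpressionMatrix(pd.DataFrame(values).T)


def sample_table(entries: list[tuple[str, str, str]], scores=None) -> pd.DataFrame:
    """Build a sample table from (sample_id, cancer_type, sample_class) rows."""
    df = pd.DataFrame(entries, columns=["sample_id", "cancer_type", "sample_class"])
    df["aneuploidy_score"] = np.nan
    if scores:
        df.loc[df["sample_id"].isin(scores), "aneuploidy_score"] = df["sample_id"].map(
            scores
        )
    return df
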