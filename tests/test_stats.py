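import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pancscreen as ps
from pancscreen.stats import PANCAN, promoter_window, significance_marker
from tests.conftest import expression_from_dict, sample_table


def exact_two_sided_p(x_ranks: tuple[int, ...], n_total: int) -> float:
    """Enumeration oracle: two-sided rank-sum p over all C(n, k) assignments."""
    k = len(x_ranks)
    u_obs = sum(x_ranks) - k * (k + 1) // 2
    us = [
        sum(c) - k * (k + 1) // 2
        for c in itertools.combinations(range(1, n_total + 1), k)
    ]
    n = len(us)
    p_le = sum(u <= u_obs for u in us) / n
    p_ge = sum(u >= u_obs for u in us) / n
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_reference_example(self):
        stat, p = ps.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert stat == 0.0

    def test_identical_samples_give_p_one(self, caplog):
        with caplog.at_level("WARNING", logger="pancscreen"):
            _, p = ps.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle_small(self):
        # spot-check a handful of arrangements against the exhaustive oracle
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_total = int(rng.integers(4, 11))
            k = int(rng.integers(1, n_total))
            x_ranks = tuple(
                sorted(rng.choice(np.arange(1, n_total + 1), size=k, replace=False))
            )
            y_ranks = [r for r in range(1, n_total + 1) if r not in x_ranks]
            _, p = ps.wilcoxon_rank_sum(list(x_ranks), y_ranks)
            assert p == pytest.approx(exact_two_sided_p(x_ranks, n_total), abs=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        _, p1 = ps.wilcoxon_rank_sum(x, y)
        _, p2 = ps.wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-14)


class TestDiffExpPerCancer:
    def test_planted_downshift_called_down(self, default_cohort):
        cfg = default_cohort.truth.config
        res = ps.diffexp_per_cancer(
            default_cohort.expression, default_cohort.samples, cfg.focal_gene
        )
        per_cancer = [r for r in res if r.cancer_type != PANCAN]
        assert len(per_cancer) == 13
        assert sum(r.direction == "down" for r in per_cancer) >= 12
        pancan = [r for r in res if r.cancer_type == PANCAN][0]
        assert pancan.direction == "down"
        assert pancan.n_a == 13 * 25

    def test_single_cancer_pancan_equals_pooled(self, small_cohort):
        one = small_cohort.samples[small_cohort.samples["cancer_type"] == "C01"]
        res = ps.diffexp_per_cancer(
            small_cohort.expression, one, small_cohort.truth.config.focal_gene,
            min_samples_per_arm=5,
        )
        by_type = {r.cancer_type: r for r in res}
        assert by_type["C01"].p_two_sided == by_type[PANCAN].p_two_sided
        assert by_type["C01"].statistic == by_type[PANCAN].statistic

    def test_absent_gene_raises(self, small_cohort):
        with pytest.raises(KeyError):
            ps.diffexp_per_cancer(small_cohort.expression, small_cohort.samples, "nope")


class TestFamilyConsistencyBinomial:
    def test_thirteen_of_thirteen_matches_printed_value(self):
        p, k, n = ps.family_consistency_binomial(["down"] * 13)
        assert (k, n) == (13, 13)
        assert p == pytest.approx((1 / 3) ** 13, rel=1e-12)

    def test_no_down_calls(self):
        p, k, n = ps.family_consistency_binomial(["up", "ns", "up"])
        assert k == 0 and p == 1.0

    def test_closed_form_two_cancers(self):
        p, _, _ = ps.family_consistency_binomial(["down", "ns"])
        assert p == pytest.approx(1 - (2 / 3) ** 2, rel=1e-12)  # 5/9

    @pytest.mark.parametrize("n", [1, 5, 13, 20])
    def test_matches_pmf_summation_oracle(self, n):
        rng = np.random.default_rng(n)
        dirs = rng.choice(["down", "up", "ns"], size=n).tolist()
        p, k, _ = ps.family_consistency_binomial(dirs)
        oracle = sum(
            math.comb(n, j) * (1 / 3) ** j * (2 / 3) ** (n - j) for j in range(k, n + 1)
        )
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            ps.family_consistency_binomial(["down", "sideways"])


class TestStratification:
    def _table(self, n, cancer="C01"):
        return sample_table(
            [(f"t{i}", cancer, ps.TUMOR) for i in range(1, n + 1)]
        )

    def test_anticorrelated_regulators(self):
        # A = 1..10, B = 10..1 over ten tumors: high = two samples, low empty
        samples = self._table(10)
        expr = expression_from_dict(
            {
                "regA": {f"t{i}": float(i) for i in range(1, 11)},
                "regB": {f"t{i}": float(11 - i) for i in range(1, 11)},
            }
        )
        strata = ps.stratify_by_regulators(expr, samples, ["regA", "regB"], 0.10)
        high = set(strata.loc[strata["stratum"] == "regulator_high", "sample_id"])
        low = set(strata.loc[strata["stratum"] == "regulator_low", "sample_id"])
        assert high == {"t10", "t1"}
        assert low == set()

    def test_single_regulator_tenth_of_twenty(self):
        samples = self._table(20)
        expr = expression_from_dict(
            {"regA": {f"t{i}": float(i) for i in range(1, 21)}}
        )
        strata = ps.stratify_by_regulators(expr, samples, ["regA"], 0.10)
        counts = strata["stratum"].value_counts()
        assert counts["regulator_high"] == 2
        assert counts["regulator_low"] == 2

    def test_all_tied_cancer_skipped(self, caplog):
        samples = self._table(10)
        expr = expression_from_dict({"regA": {f"t{i}": 1.0 for i in range(1, 11)}})
        with caplog.at_level("WARNING", logger="pancscreen"):
            strata = ps.stratify_by_regulators(expr, samples, ["regA"], 0.10)
        assert strata.empty
        assert any("overlap" in m for m in caplog.messages)

    def test_too_few_samples_skipped(self, caplog):
        samples = self._table(5)
        expr = expression_from_dict(
            {"regA": {f"t{i}": float(i) for i in range(1, 6)}}
        )
        with caplog.at_level("WARNING", logger="pancscreen"):
            strata = ps.stratify_by_regulators(expr, samples, ["regA"], 0.10)
        assert strata.empty

    def test_strata_always_disjoint_and_high_large_enough(self, default_cohort):
        genes = default_cohort.expression.gene_ids
        strata = ps.stratify_by_regulators(
            default_cohort.expression, default_cohort.samples, [genes[10], genes[20]]
        )
        for cancer, grp in strata.groupby("cancer_type"):
            high = set(grp.loc[grp["stratum"] == "regulator_high", "sample_id"])
            low = set(grp.loc[grp["stratum"] == "regulator_low", "sample_id"])
            assert not (high & low)
            assert len(high) >= math.ceil(0.10 * len(grp))


class TestCompareStrata:
    @staticmethod
    def _conditional_cohort(seed: int) -> tuple:
        """Cohort whose focal downshift applies only in regulator-high tumors."""
        cfg = ps.CohortConfig(
            n_cancers=4, n_healthy=25, n_tumor=25, n_genes=60,
            n_gene_sets=2, set_size_range=(5, 10),
            focal_downshift=0.0, rewiring_weight=0.0, aneuploidy_coupling=0.0,
            rng_seed=seed,
        )
        c = ps.generate_cohort(cfg)
        regulators = [cfg.gene_ids[5], cfg.gene_ids[6]]
        strata = ps.stratify_by_regulators(c.expression, c.samples, regulators)
        data = c.expression.data.copy()
        high_ids = strata.loc[strata["stratum"] == "regulator_high", "sample_id"]
        data.loc[cfg.focal_gene, high_ids] = (
            data.loc[cfg.focal_gene, high_ids] - 1.5
        ).clip(lower=0.0)
        return ps.ExpressionMatrix(data), c.samples, strata, cfg.focal_gene

    def test_conditional_downshift_detected_only_in_high_stratum(self):
        from pancscreen._rng import child_seed

        hits_high, hits_low = 0, 0
        n_seeds = 20
        for r in range(n_seeds):
            expr, samples, strata, focal = self._conditional_cohort(
                child_seed(0, "strata-recovery", str(r))
            )
            table = ps.compare_strata_expression(expr, samples, strata, focal)
            pan = table[table["cancer_type"] == PANCAN].set_index("stratum")
            hits_high += pan.loc["regulator_high", "p_two_sided"] < 0.05
            hits_low += pan.loc["regulator_low", "p_two_sided"] < 0.05
        assert hits_high >= 0.8 * n_seeds
        assert hits_low <= 0.5 * n_seeds

    def test_empty_stratum_marked_untestable(self, small_cohort):
        strata = pd.DataFrame(
            {
                "sample_id": ["C01_T001", "C01_T002"],
                "cancer_type": ["C01", "C01"],
                "stratum": ["regulator_high", "other"],
            }
        )
        table = ps.compare_strata_expression(
            small_cohort.expression,
            small_cohort.samples,
            strata,
            small_cohort.truth.config.focal_gene,
        )
        low = table[(table["stratum"] == "regulator_low") & (table["cancer_type"] == "C01")]
        assert not low["testable"].iloc[0]
        assert low["direction"].iloc[0] == "untestable"


class TestOncogeneEffect:
    def test_normalization_arithmetic(self):
        # TPM 3 -> log2(4) = 2; matched control mean log-TPM 1 -> normalized 1.0
        expr = expression_from_dict(
            {
                "g1": {
                    "cl_Empty_48h_r1": 1.0,
                    "cl_Empty_48h_r2": 1.0,
                    "cl_ONC_48h_r1": np.log2(3 + 1),
                    "cl_ONC_48h_r2": 2.0,
                }
            }
        )
        design = pd.DataFrame(
            {
                "sample_id": list(expr.sample_ids),
                "cell_line": "cl",
                "condition": ["Empty", "Empty", "ONC", "ONC"],
                "timepoint": 48,
                "replicate": [1, 2, 1, 2],
            }
        )
        res = ps.oncogene_effect_test(expr, design, "g1")
        assert res["ONC"]["normalized"]["cl_ONC_48h_r1"] == pytest.approx(1.0)
        assert res["ONC"]["control_normalized"].abs().max() == pytest.approx(0.0)

    def test_planted_factor_recovered(self):
        from pancscreen._rng import child_seed

        hits = {"CCNE1": 0, "CDC25A": 0, "MYC": 0}
        n_seeds = 20
        for r in range(n_seeds):
            cfg = ps.OverexpressionConfig(
                n_genes=100, rng_seed=child_seed(0, "oe-recovery", str(r))
            )
            expr, design, truth = ps.generate_overexpression_experiment(cfg)
            res = ps.oncogene_effect_test(expr, design, truth["focal_gene"])
            for onc in hits:
                hits[onc] += res[onc]["p"] < 0.05
        assert hits["CCNE1"] >= 0.8 * n_seeds
        assert hits["CDC25A"] >= 0.8 * n_seeds
        assert hits["MYC"] <= 0.2 * n_seeds

    def test_missing_control_arm_raises(self):
        expr = expression_from_dict({"g1": {"a": 1.0, "b": 2.0}})
        design = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "cell_line": "cl",
                "condition": ["ONC", "ONC"],
                "timepoint": 48,
                "replicate": [1, 2],
            }
        )
        with pytest.raises(ValueError, match="Empty control"):
            ps.oncogene_effect_test(expr, design, "g1")


class TestPromoterMethylation:
    def _fixture(self, strand="+"):
        ann = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "length_bp": [5000],
                "chrom": ["chr1"],
                "tss": [10000],
                "strand": [strand],
            }
        )
        samples = sample_table(
            [("t1", "C01", ps.TUMOR), ("h1", "C01", ps.HEALTHY)]
        )
        return ann, samples

    def test_window_membership_and_median(self):
        ann, samples = self._fixture("+")
        meth = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "chrom": "chr1",
                "position": [9000, 9900, 10050],
                "t1": [0.8, 0.6, 0.9],
                "h1": [0.8, 0.6, 0.9],
            }
        )
        medians, table = ps.promoter_methylation_test(meth, ann, samples, "g1", 1500)
        assert medians["t1"] == pytest.approx(0.7)  # median of {0.8, 0.6}

    def test_minus_strand_mirrored(self):
        ann, samples = self._fixture("-")
        meth = pd.DataFrame(
            {
                "probe_id": ["p1"],
                "chrom": "chr1",
                "position": [10100],  # TSS + 100, upstream on the - strand
                "t1": [0.5],
                "h1": [0.5],
            }
        )
        medians, _ = ps.promoter_methylation_test(meth, ann, samples, "g1", 1500)
        assert medians is not None and medians["t1"] == pytest.approx(0.5)
        start, end = promoter_window(10000, "-", 1500)
        assert start == 10001 and end == 11501

    def test_no_probes_untestable(self, caplog):
        ann, samples = self._fixture("+")
        meth = pd.DataFrame(
            {
                "probe_id": ["p1"],
                "chrom": "chr1",
                "position": [99999],
                "t1": [0.5],
                "h1": [0.5],
            }
        )
        with caplog.at_level("WARNING", logger="pancscreen"):
            medians, table = ps.promoter_methylation_test(meth, ann, samples, "g1")
        assert medians is None and table.empty

    def test_runs_on_synthetic_cohort(self, small_cohort):
        medians, table = ps.promoter_methylation_test(
            small_cohort.methylation,
            small_cohort.annotation,
            small_cohort.samples,
            small_cohort.truth.config.focal_gene,
        )
        if medians is not None:
            assert ((medians >= 0) & (medians <= 1)).all()
            assert set(table["cancer_type"]) <= set(
                small_cohort.truth.config.cancer_types
            )


def test_significance_markers():
    assert significance_marker(5e-5) == "****"
    assert significance_marker(0.03) == "*"
    assert significance_marker(0.2) == "ns"
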