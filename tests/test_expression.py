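"""Comparative-CT quantification, ANOVA significance and regulation classes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bgcbound.expression import (DetectionStatus, ExpressionError, RegClass,
                                 analyze_locus, anova_p, classify_gene,
                                 relative_expression)
from bgcbound.simulate import (FIG2B_CLASSES, ExpressionDesign, fig2b_design,
                               generate_ct_table)


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["strain", "gene", "bio_rep", "tech_rep", "ct"])


def noise_free_table(ct_target_cal, ct_target_case, ct_ref=20.0, n_bio=3, n_tech=3):
    rows = []
    for strain, ct_t in (("wt", ct_target_cal), ("mut", ct_target_case)):
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append((strain, "tgt", b, t, ct_t))
                rows.append((strain, "ref", b, t, ct_ref))
    return ct_frame(rows)


class TestRelativeExpression:
    def test_identical_cts_give_fold_change_one(self):
        df = noise_free_table(24.0, 24.0)
        fold, rel_case, rel_cal = relative_expression(df, "tgt", "ref", "mut", "wt")
        assert fold == pytest.approx(1.0)
        assert np.allclose(rel_case, 1.0) and np.allclose(rel_cal, 1.0)

    def test_four_cycle_shift_gives_sixteenfold_repression(self):
        """dCT 4 vs 8 -> ddCT 4 -> fold change 2^-4 = 0.0625."""
        df = noise_free_table(24.0, 28.0)
        fold, _, _ = relative_expression(df, "tgt", "ref", "mut", "wt")
        assert fold == pytest.approx(0.0625)

    def test_constant_ct_offset_on_one_strain_cancels(self):
        df = noise_free_table(24.0, 28.0)
        shifted = df.copy()
        shifted.loc[shifted["strain"] == "mut", "ct"] += 3.0
        f1, _, _ = relative_expression(df, "tgt", "ref", "mut", "wt")
        f2, _, _ = relative_expression(shifted, "tgt", "ref", "mut", "wt")
        assert f1 == pytest.approx(f2)

    def test_undetermined_reference_is_hard_error(self):
        df = noise_free_table(24.0, 28.0)
        df.loc[(df["strain"] == "wt") & (df["gene"] == "ref"), "ct"] = float("nan")
        with pytest.raises(ExpressionError, match="reference"):
            relative_expression(df, "tgt", "ref", "mut", "wt")


class TestAnova:
    def test_identical_groups_give_p_one(self):
        assert anova_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_two_group_anova_equals_pooled_t_test(self):
        """t^2 = F: the two-group ANOVA p matches the two-sided t-test p."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(0, 1, int(rng.integers(2, 8)))
            b = rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(2, 8)))
            p_f = anova_p(a, b)
            p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_separated_groups_highly_significant(self):
        a, b = [1.0, 1.1, 0.9], [0.05, 0.04, 0.06]
        p = anova_p(a, b)
        # independent route: F statistic and its survival function directly
        n = 3
        ga, gb = np.mean(a), np.mean(b)
        grand = np.mean(a + b)
        ss_between = n * ((ga - grand) ** 2 + (gb - grand) ** 2)
        ss_within = sum((x - ga) ** 2 for x in a) + sum((x - gb) ** 2 for x in b)
        f_stat = ss_between / (ss_within / 4)
        assert p == pytest.approx(float(stats.f.sf(f_stat, 1, 4)), rel=1e-9)
        assert p < 0.001

    def test_single_value_groups_rejected(self):
        with pytest.raises(ExpressionError):
            anova_p([1.0], [1.0, 2.0])


class TestClassify:
    @pytest.mark.parametrize("fc,p,expected", [
        (0.0625, 0.001, RegClass.ABOLISHED),
        (0.1, 0.01, RegClass.ABOLISHED),
        (0.4, 0.01, RegClass.DOWNREGULATED),
        (2 / 3, 0.04, RegClass.DOWNREGULATED),
        (0.9, 0.4, RegClass.UNCHANGED),
        (0.9, 0.01, RegClass.UNCHANGED),    # significant but inside the dead band
        (0.05, 0.6, RegClass.UNCHANGED),    # large change, not significant
        (1.5, 0.01, RegClass.UPREGULATED),
        (3.0, 0.001, RegClass.UPREGULATED),
    ])
    def test_fold_change_bands(self, fc, p, expected):
        assert classify_gene(fc, p) is expected

    def test_detection_flags_short_circuit(self):
        assert classify_gene(float("nan"), float("nan"),
                             DetectionStatus.NOT_IN_CALIBRATOR) is RegClass.NOT_EXPRESSED
        assert classify_gene(float("nan"), float("nan"),
                             DetectionStatus.NOT_IN_CASE) is RegClass.ABOLISHED

    def test_classes_partition_the_space(self):
        """Every (fc, p) combination maps to exactly one class."""
        for fc in (0.01, 0.1, 0.1001, 0.5, 2 / 3, 0.7, 1.0, 1.49, 1.5, 4.0):
            for p in (1e-6, 0.049, 0.05, 0.51, float("nan")):
                assert isinstance(classify_gene(fc, p), RegClass)


class TestAnalyzeLocus:
    def test_single_gene_table_yields_single_result(self):
        df = noise_free_table(24.0, 28.0)
        results = analyze_locus(df, "ref", "mut", "wt")
        assert len(results) == 1
        assert results[0].reg_class is RegClass.ABOLISHED

    def test_missing_reference_gene_is_an_error(self):
        df = noise_free_table(24.0, 28.0)
        df = df[df["gene"] != "ref"]
        with pytest.raises(ExpressionError, match="reference"):
            analyze_locus(df, "ref", "mut", "wt")

    def test_fig2b_classes_recovered(self, fig2b_table):
        results = analyze_locus(fig2b_table, "GAPDH", "dmrpigB", "M7")
        by_gene = {r.gene: r.reg_class for r in results}
        for cls, genes in FIG2B_CLASSES.items():
            for g in genes:
                assert by_gene[g] is RegClass(cls), g

    def test_fig2b_class_counts_stable_across_seeds(self):
        """Seeds 1..10: six abolished, six downregulated, one silent gene."""
        for seed in range(1, 11):
            table = generate_ct_table(fig2b_design(seed))
            results = analyze_locus(table, "GAPDH", "dmrpigB", "M7")
            counts = {}
            for r in results:
                counts[r.reg_class] = counts.get(r.reg_class, 0) + 1
            assert counts[RegClass.ABOLISHED] == 6
            assert counts[RegClass.DOWNREGULATED] == 6
            assert counts[RegClass.NOT_EXPRESSED] == 1
            interior = {"mrpigC", "mrpigJ", "mrpigK", "mrpigL"}
            unchanged = {r.gene for r in results if r.reg_class is RegClass.UNCHANGED}
            assert interior <= unchanged

    def test_null_p_values_are_uniform(self):
        """1000 independent fold-change-1 experiments: p passes a KS test.

        Genes assayed on the same plate share the reference gene's noise,
        so independence requires one simulated experiment per draw.
        """
        ps = []
        for seed in range(1000):
            table = generate_ct_table(
                ExpressionDesign(fold_changes={"gX": 1.0}, seed=10_000 + seed))
            ps.append(analyze_locus(table, "GAPDH", "dmrpigB", "M7")[0].p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
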