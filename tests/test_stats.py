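"""Cohort diagnostics: ANOVA/Tukey/effect size, grade correlation, ROC
cutoff selection, DeLong intervals, confusion metrics and the full report."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from echohet import (
    CohortError,
    ConfusionTable,
    auroc,
    confusion_metrics,
    delong_auc_variance,
    grade_correlation,
    make_cohort,
    one_way_anova,
    run_group_report,
    select_cutoff,
)
from echohet.stats import effect_band
from echohet.synthetic import generate_cohort

import oracles


def cohort_from(groups_scores: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for g, scores in groups_scores.items():
        for s in scores:
            rows.append({"patient_id": f"{g}-{len(rows)}", "group": g, "score_pct": s})
    return make_cohort(pd.DataFrame(rows))


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova([[1, 3], [1, 3]])
        assert res.F == 0.0
        assert res.eta_sq == 0.0
        assert res.p == 1.0

    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert res.eta_sq == pytest.approx(1.5 / 5.5, abs=1e-12)
        assert res.effect_band == "large"
        assert res.df_between == 1 and res.df_within == 4

    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(10, 3, size=rng.integers(3, 15))
            b = rng.normal(12, 3, size=rng.integers(3, 15))
            t, _ = sps.ttest_ind(a, b)
            assert one_way_anova([a, b]).F == pytest.approx(t**2, rel=1e-10)

    def test_eta_sq_affine_invariant(self, rng):
        groups = [rng.normal(m, 2, size=10) for m in (5.0, 7.0, 9.0)]
        base = one_way_anova(groups).eta_sq
        shifted = one_way_anova([3.5 * g - 11.0 for g in groups]).eta_sq
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_effect_bands_follow_cut_points(self):
        assert effect_band(0.005) == "negligible"
        assert effect_band(0.01) == "small"
        assert effect_band(0.06) == "medium"
        assert effect_band(0.14) == "large"

    def test_tukey_p_at_least_unadjusted_t(self, rng):
        """Tukey's familywise adjustment can only raise pairwise p-values
        relative to the unadjusted pooled-variance (LSD) t-test."""
        for _ in range(20):
            groups = [
                rng.normal(rng.uniform(8, 14), 2, size=rng.integers(4, 12))
                for _ in range(rng.integers(2, 6))
            ]
            res = one_way_anova(groups)
            names = [f"group{i}" for i in range(len(groups))]
            ns = [len(g) for g in groups]
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / res.df_within
            for pair in res.tukey:
                i, j = names.index(pair.group_a), names.index(pair.group_b)
                t = abs(pair.mean_diff) / np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
                p_t = 2 * sps.t.sf(t, res.df_within)
                assert pair.p_adj >= p_t - 1e-12

    def test_tukey_cross_checked_against_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 2.0, size=n) for m, n in ((10, 8), (11, 12), (13, 7))]
        res = one_way_anova(groups, names=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [len(g) for g in groups])
        sm = pairwise_tukeyhsd(data, labels)
        # statsmodels' psturng table is only ~1e-3 accurate
        np.testing.assert_allclose(
            [p.p_adj for p in res.tukey], sm.pvalues, atol=5e-3
        )
        np.testing.assert_allclose(
            [p.mean_diff for p in res.tukey], sm.meandiffs, rtol=1e-10
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(CohortError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(CohortError):
            one_way_anova([[1, 2], [5]])


class TestCorrelation:
    def test_perfect_linear_relation(self):
        cohort = cohort_from(
            {"normal": [0.0, 0.0], "II-B": [1.0], "III-B": [2.0], "III-M": [3.0]}
        )
        res = grade_correlation(cohort)
        assert res.r == 1.0
        assert res.p == 0.0

    def test_hand_computed_pearson(self):
        # x = grade codes {1,2,3,4}, y = {2,4,5,4}:
        # r = 3.5 / sqrt(5 * 4.75) = 0.7182
        x = np.array([1, 2, 3, 4], dtype=float)
        y = np.array([2, 4, 5, 4], dtype=float)
        cohort = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "group": ["II-B", "III-B", "III-M", "V/VI-M"],
                "score_pct": y,
            }
        )
        res = grade_correlation(make_cohort(cohort))
        assert res.r == pytest.approx(3.5 / np.sqrt(5 * 4.75), rel=1e-12)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_constant_grades_undefined(self):
        cohort = cohort_from({"III-B": [1.0, 2.0, 3.0]})
        with pytest.raises(CohortError, match="constant"):
            grade_correlation(cohort)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_all_ties_give_chance(self):
        assert auroc([5, 5, 5, 5], [False, True, False, True]) == 0.5

    def test_interleaved_example(self):
        scores = [3, 5, 7, 2, 4, 6]
        labels = [True, True, True, False, False, False]
        assert auroc(scores, labels) == pytest.approx(6 / 9, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(CohortError):
            auroc([1, 2, 3], [True, True, True])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n_pos, n_neg = rng.integers(2, 25, size=2)
            pos = np.round(rng.uniform(0, 10, n_pos), 1)
            neg = np.round(rng.uniform(0, 10, n_neg), 1)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            assert auroc(scores, labels) == pytest.approx(
                oracles.pairwise_auroc(pos, neg), abs=1e-12
            )


class TestDeLong:
    # reference values computed with pROC (R): roc(controls=neg, cases=pos),
    # var(..., method="delong"), ci.auc(..., method="delong")
    PROC_POS = [3.1, 4.5, 5.2, 6.6, 7.0, 8.3, 5.9, 6.1]
    PROC_NEG = [1.2, 2.4, 3.3, 4.1, 2.8, 5.0, 3.9]
    PROC_AUC = 0.9107142857142857
    PROC_VAR = 0.006331997084548107

    def test_matches_proc_reference(self):
        auc, var = delong_auc_variance(np.array(self.PROC_POS), np.array(self.PROC_NEG))
        assert auc == pytest.approx(self.PROC_AUC, rel=1e-12)
        assert var == pytest.approx(self.PROC_VAR, rel=1e-9)

    def test_ci_contains_auc_and_shrinks_with_n(self, rng):
        small = select_cutoff(
            np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 20)],
            np.r_[np.ones(20, bool), np.zeros(20, bool)],
        )
        big = select_cutoff(
            np.r_[rng.normal(1, 1, 500), rng.normal(0, 1, 500)],
            np.r_[np.ones(500, bool), np.zeros(500, bool)],
        )
        for res in (small, big):
            assert res.ci95[0] <= res.auroc <= res.ci95[1]
        assert (big.ci95[1] - big.ci95[0]) < (small.ci95[1] - small.ci95[0])


class TestSelectCutoff:
    def test_perfect_separation_smallest_attaining_threshold(self):
        res = select_cutoff([1, 2, 10, 11], [False, False, True, True])
        assert res.cutoff == 10
        assert res.youden_j == pytest.approx(1.0)
        assert res.metrics.da.pct == 100.0

    def test_exhaustive_scan_example(self):
        res = select_cutoff([5, 6, 7, 1, 2, 6], [True, True, True, False, False, False])
        assert res.cutoff == 5
        assert res.youden_j == pytest.approx(2 / 3, rel=1e-12)

    def test_returned_j_dominates_all_observed_thresholds(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.uniform(0, 50, n), 1)
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = select_cutoff(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            for t in np.unique(scores):
                j = (pos >= t).mean() + (neg < t).mean() - 1.0
                assert res.youden_j >= j - 1e-12

    def test_da_is_prevalence_weighted_sens_spec(self, rng):
        scores = np.round(rng.uniform(0, 50, 60), 1)
        labels = rng.uniform(size=60) < 0.4
        res = select_cutoff(scores, labels)
        m = res.metrics
        p, n = res.n_pos, res.n_neg
        da = (m.sensitivity.pct * p + m.specificity.pct * n) / (p + n)
        assert m.da.pct == pytest.approx(da, rel=1e-12)


class TestConfusionMetrics:
    def test_published_counts_round_to_reported_percentages(self):
        m = confusion_metrics(ConfusionTable(tp=83, fn=31, tn=78, fp=30))
        assert round(m.sensitivity.pct, 1) == 72.8
        assert round(m.specificity.pct, 1) == 72.2
        # 83/113 = 73.4513; the source table prints 73.4 (rounded down)
        assert m.ppv.pct == pytest.approx(100 * 83 / 113, rel=1e-12)
        assert round(m.npv.pct, 1) == 71.6
        assert round(m.da.pct, 1) == 72.5
        assert (m.da.numerator, m.da.denominator) == (161, 222)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionTable(tp=10, fn=0, tn=10, fp=0))
        for metric in (m.sensitivity, m.specificity, m.ppv, m.npv, m.da):
            assert metric.pct == 100.0

    def test_undefined_ppv_flagged_not_fatal(self):
        m = confusion_metrics(ConfusionTable(tp=0, fn=5, tn=5, fp=0))
        assert m.ppv.pct is None
        assert "undefined" in str(m.ppv)
        assert m.specificity.pct == 100.0


class TestGroupReport:
    def test_default_synthetic_cohort_is_fully_reported(self):
        report = run_group_report(generate_cohort(seed=11))
        assert len(report.comparisons) == 6
        assert list(report.group_summary["group"]) == [
            "normal", "II-B", "III-B", "III-M", "V/VI-M",
        ]
        assert len(report.anova.tukey) == 6  # four nodule groups -> 6 pairs
        # each row's DA must be recomputable from its own counts
        for row in report.comparisons:
            c = row.roc.confusion
            assert row.roc.metrics.da.pct == pytest.approx(
                100.0 * (c.tp + c.tn) / c.total, rel=1e-12
            )

    def test_identical_pooled_distributions_are_chance_level(self, rng):
        scores = list(rng.normal(30, 5, 80))
        cohort = cohort_from({"III-B": scores[:40], "III-M": scores[:40]})
        report = run_group_report(
            cohort, comparisons=[("b vs m", ("III-B",), ("III-M",))]
        )
        assert report.comparisons[0].roc.auroc == pytest.approx(0.5, abs=1e-12)

    def test_perfectly_separated_groups_reach_full_accuracy(self):
        cohort = cohort_from(
            {"III-B": [10, 11, 12, 13], "III-M": [40, 41, 42, 43]}
        )
        report = run_group_report(cohort)
        rows = {r.name: r for r in report.comparisons}
        assert rows["III-B vs. III-M"].roc.metrics.da.pct == 100.0
        # comparisons naming absent groups are skipped, not run on partial pools
        assert len(report.skipped) == 5

    def test_missing_normal_group_skips_its_comparisons(self, caplog):
        import logging

        cohort = generate_cohort(seed=3)
        cohort = cohort[cohort["group"] != "normal"]
        with caplog.at_level(logging.WARNING, logger="echohet.stats"):
            report = run_group_report(cohort)
        assert len(report.comparisons) == 4
        assert len(report.skipped) == 2
        assert all(name.startswith("Normal/") for name in report.skipped)

    def test_strict_mode_raises_on_missing_group(self):
        cohort = generate_cohort(seed=3)
        cohort = cohort[cohort["group"] != "normal"]
        with pytest.raises(CohortError):
            run_group_report(cohort, strict=True)


class TestCohortValidation:
    def test_duplicate_patients_rejected(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "a"], "group": ["II-B", "III-B"], "score_pct": [1, 2]}
        )
        with pytest.raises(CohortError, match="unique"):
            make_cohort(df)

    def test_unknown_group_label_lists_valid_ones(self):
        df = pd.DataFrame(
            {"patient_id": ["a"], "group": ["IV-B"], "score_pct": [1.0]}
        )
        with pytest.raises(CohortError, match="valid labels"):
            make_cohort(df)
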