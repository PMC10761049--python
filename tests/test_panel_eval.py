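"""ROC layer tests with independent oracles: concordant-pair counting for
the AUC, exhaustive threshold search for the Youden cutoff."""

import numpy as np
import pandas as pd
import pytest

from methpanel.panel_eval import (
    MarkerPanelClassifier,
    classify,
    combine_markers,
    compare_afp,
    group_tests,
    roc_analysis,
    split_cohort,
    subgroup_performance,
)


def auc_by_pair_counting(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


def youden_by_exhaustive_search(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = (-np.inf, np.inf)
    for t in np.unique(scores):
        calls = scores >= t
        sens = calls[labels].mean()
        spec = (~calls[~labels]).mean()
        j = sens + spec - 1
        # ties resolved toward the smallest threshold
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t < best[1]):
            best = (j, t)
    return best


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 100.0
        assert (roc.ci_low, roc.ci_high) == (100.0, 100.0)
        assert roc.youden_sens == 100.0 and roc.youden_spec == 100.0
        assert roc.youden_index == pytest.approx(1.0)

    def test_hand_counted_half_auc(self):
        roc = roc_analysis([3, 1, 2, 4], [False, True, False, True])
        assert roc.auc == pytest.approx(50.0)

    def test_auc_equals_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            scores = rng.integers(0, 10, n).astype(float)  # ties likely
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12
            )

    def test_youden_equals_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(6, 60))
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(scores, labels)
            j_best, t_best = youden_by_exhaustive_search(scores, labels)
            assert roc.youden_index == pytest.approx(j_best, abs=1e-12)
            assert roc.youden_cutoff == pytest.approx(t_best)

    def test_classify_at_cutoff_reproduces_reported_operating_point(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.2, 1, 50)])
        labels = np.arange(100) >= 50
        roc = roc_analysis(scores, labels)
        calls = classify(scores, roc.youden_cutoff)
        assert 100.0 * calls[labels].mean() == pytest.approx(roc.youden_sens)
        assert 100.0 * (~calls[~labels]).mean() == pytest.approx(roc.youden_spec)

    def test_delong_ci_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (50, 200, 800):
            scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
            labels = np.arange(2 * n) >= n
            roc = roc_analysis(scores, labels)
            assert roc.ci_low <= roc.auc <= roc.ci_high
            widths.append(roc.ci_high - roc.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestClassify:
    def test_inclusive_boundary(self):
        assert classify([19.9, 20.0, 21.0], 20.0).tolist() == [False, True, True]

    def test_all_below_cutoff(self):
        assert classify([1, 2, 3], 10).sum() == 0


class TestSplitCohort:
    @staticmethod
    def cohort(n_hcc=173, n_cld=199, n_normal=98):
        return pd.DataFrame(
            {"group": ["HCC"] * n_hcc + ["CLD"] * n_cld + ["Normal"] * n_normal}
        )

    def test_published_cohort_sizes(self):
        out = split_cohort(self.cohort(), seed=0)
        counts = out.groupby(["group", "split"]).size()
        assert counts["HCC", "training"] == 116 and counts["HCC", "validation"] == 57
        assert counts["CLD", "training"] == 133 and counts["CLD", "validation"] == 66
        assert counts["Normal", "training"] == 66 and counts["Normal", "validation"] == 32

    def test_three_records_split_two_one(self):
        out = split_cohort(pd.DataFrame({"group": ["HCC"] * 3}), seed=1)
        assert (out["split"] == "training").sum() == 2

    def test_same_seed_reproduces(self):
        a = split_cohort(self.cohort(30, 30, 30), seed=5)
        b = split_cohort(self.cohort(30, 30, 30), seed=5)
        assert (a["split"] == b["split"]).all()


class TestMarkerCombination:
    @staticmethod
    def two_marker_cohort(seed, n=300, informative=(True, True)):
        rng = np.random.default_rng(seed)
        labels = np.arange(n) < n // 2
        levels = []
        for useful in informative:
            shift = 1.2 if useful else 0.0
            levels.append(np.exp(rng.normal(0, 1, n) + shift * labels))
        return levels[0], levels[1], labels

    def test_constant_marker_reduces_to_single_marker_roc(self):
        a, _, labels = self.two_marker_cohort(1)
        const = np.full_like(a, 0.5)
        scores, _ = combine_markers(a, const, labels)
        assert roc_analysis(scores, labels).auc == pytest.approx(
            roc_analysis(a, labels).auc, abs=1e-9
        )

    def test_identical_markers_equal_single_marker(self):
        a, _, labels = self.two_marker_cohort(2)
        scores, _ = combine_markers(a, a, labels)
        assert roc_analysis(scores, labels).auc == pytest.approx(
            roc_analysis(a, labels).auc, abs=1e-9
        )

    def test_combination_beats_each_single_marker(self):
        a, b, labels = self.two_marker_cohort(3)
        scores, _ = combine_markers(a, b, labels)
        combined = roc_analysis(scores, labels).auc
        assert combined > roc_analysis(a, labels).auc
        assert combined > roc_analysis(b, labels).auc

    def test_separable_data_falls_back_to_rank_average(self):
        labels = np.arange(40) < 20
        a = np.where(labels, 10.0, 0.1) * (1 + 0.01 * np.arange(40))
        b = np.ones(40)
        scores, est = combine_markers(a, b, labels)
        assert est.fallback_
        assert roc_analysis(scores, labels).auc == 100.0

    def test_estimator_api_roundtrip(self):
        a, b, labels = self.two_marker_cohort(4)
        X = np.column_stack([a, b])
        est = MarkerPanelClassifier()
        assert est.get_params() == {"method": "logistic", "eps": 1e-6}
        est.fit(X, labels)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert est.predict(X).mean() == pytest.approx(0.5, abs=0.15)

    def test_or_rule_scores_one_at_marker_cutoff(self):
        a, b, labels = self.two_marker_cohort(5)
        X = np.column_stack([a, b])
        est = MarkerPanelClassifier(method="or").fit(X, labels)
        either_positive = (X >= est.cutoffs_).any(axis=1)
        np.testing.assert_array_equal(est.decision_function(X) >= 1.0, either_positive)


def clinical_frame(stage_counts, n_cld, n_normal, tumour_counts=None):
    """Build an HCC/CLD/Normal clinical table with given stage counts."""
    rows = []
    for stage, count in stage_counts.items():
        for _ in range(count):
            rows.append({"group": "HCC", "cnlc_stage": stage,
                         "tumour_count": "", "single_tumour_size": ""})
    for _ in range(n_cld):
        rows.append({"group": "CLD", "cnlc_stage": "",
                     "tumour_count": "", "single_tumour_size": ""})
    for _ in range(n_normal):
        rows.append({"group": "Normal", "cnlc_stage": "",
                     "tumour_count": "", "single_tumour_size": ""})
    df = pd.DataFrame(rows)
    if tumour_counts is not None:
        df.loc[df["group"] == "HCC", "tumour_count"] = tumour_counts
    return df


class TestSubgroupPerformance:
    def test_stage_sensitivity_from_counts(self):
        records = clinical_frame({"I": 66}, n_cld=0, n_normal=10)
        calls = np.array([True] * 50 + [False] * 16 + [False] * 10)
        table = subgroup_performance(calls, records)
        row = table[table["stratum"] == "stage I"].iloc[0]
        assert (row["numerator"], row["denominator"]) == (50, 66)
        assert row["percent"] == 75.76

    def test_zero_positives_in_controls_is_full_specificity(self):
        records = clinical_frame({"I": 2}, n_cld=5, n_normal=5)
        calls = np.array([True, True] + [False] * 10)
        table = subgroup_performance(calls, records)
        combined = table[table["stratum"] == "non-HCC combined"].iloc[0]
        assert combined["percent"] == 100.0

    def test_multi_tumour_sensitivity(self):
        records = clinical_frame({"I": 67}, n_cld=0, n_normal=0,
                                 tumour_counts=[2] * 67)
        calls = np.array([True] * 62 + [False] * 5)
        table = subgroup_performance(calls, records)
        row = table[table["stratum"] == "multiple tumours"].iloc[0]
        assert row["percent"] == 92.54

    def test_empty_stratum_reports_na(self):
        records = clinical_frame({"I": 2}, n_cld=1, n_normal=1)
        table = subgroup_performance(np.zeros(4, bool), records)
        row = table[table["stratum"] == "stage II"].iloc[0]
        assert row["denominator"] == 0 and pd.isna(row["percent"])

    def test_percentages_recompute_from_reported_counts(self, msp_cohort):
        _, clinical, _ = msp_cohort
        rng = np.random.default_rng(0)
        calls = rng.random(len(clinical)) < 0.5
        table = subgroup_performance(calls, clinical)
        for row in table.itertuples():
            if row.denominator:
                assert row.percent == round(100.0 * row.numerator / row.denominator, 2)


class TestCompareAfp:
    @staticmethod
    def afp_cohort():
        """73 HCC (23 I / 11 II / 39 III-IV) + 31 CLD with AFP values placed
        so the fixed 20 ng/ml cutoff and a 93.55%-specificity-matched cutoff
        produce hand-computable contingencies."""
        hcc_stage = ["I"] * 23 + ["II"] * 11 + ["III-IV"] * 39
        afp_hcc = (
            [300.0] * 11 + [100.0] * 7 + [5.0] * 5          # stage I
            + [300.0] * 6 + [100.0] * 4 + [5.0] * 1         # stage II
            + [300.0] * 28 + [100.0] * 7 + [5.0] * 4        # stage III-IV
        )
        afp_cld = [300.0] * 2 + [100.0] * 7 + [5.0] * 22
        records = pd.DataFrame(
            {"group": ["HCC"] * 73 + ["CLD"] * 31,
             "cnlc_stage": hcc_stage + [""] * 31,
             "tumour_count": "", "single_tumour_size": ""}
        )
        return np.array(afp_hcc + afp_cld), records

    def test_fixed_cutoff_20_contingencies(self):
        afp, records = self.afp_cohort()
        report = compare_afp(afp, records, fixed_cutoffs=(20.0,))
        fixed = report[report["cutoff_kind"] == "fixed"]
        get = lambda s: fixed[fixed["stratum"] == s].iloc[0]["percent"]
        assert get("all") == 86.3
        assert get("stage I") == 78.26
        assert get("stage II") == 90.91
        assert get("stage III-IV") == 89.74
        assert get("non-HCC combined") == 70.97

    def test_matched_specificity_threshold(self):
        afp, records = self.afp_cohort()
        report = compare_afp(afp, records, fixed_cutoffs=(20.0,),
                             matched_spec_target=93.55)
        matched = report[report["cutoff_kind"] == "matched"]
        assert matched["cutoff"].iloc[0] == 300.0  # smallest attaining target
        get = lambda s: matched[matched["stratum"] == s].iloc[0]["percent"]
        assert get("all") == 61.64
        assert get("stage I") == 47.83
        assert get("stage II") == 54.55
        assert get("stage III-IV") == 71.79
        assert get("non-HCC combined") == 93.55

    def test_unattainable_target_reports_infinite_threshold(self):
        afp = np.array([5.0, 5.0, 5.0, 100.0])
        records = pd.DataFrame({"group": ["HCC", "HCC", "HCC", "CLD"],
                                "cnlc_stage": ["I", "I", "II", ""],
                                "tumour_count": "", "single_tumour_size": ""})
        report = compare_afp(afp, records, fixed_cutoffs=(),
                             matched_spec_target=200.0)
        matched = report[report["cutoff_kind"] == "matched"]
        assert np.isinf(matched["cutoff"].iloc[0])
        assert matched[matched["stratum"] == "all"].iloc[0]["percent"] == 0.0

    def test_zero_afp_controls_give_full_specificity(self):
        afp = np.array([100.0, 0.0, 0.0])
        records = pd.DataFrame({"group": ["HCC", "CLD", "Normal"],
                                "cnlc_stage": ["I", "", ""],
                                "tumour_count": "", "single_tumour_size": ""})
        report = compare_afp(afp, records, fixed_cutoffs=(20.0,))
        row = report[(report["cutoff_kind"] == "fixed")
                     & (report["stratum"] == "non-HCC combined")].iloc[0]
        assert row["percent"] == 100.0


class TestGroupTests:
    def test_identical_two_groups_p_one(self):
        vals = [1, 2, 3, 1, 2, 3]
        groups = ["a"] * 3 + ["b"] * 3
        assert group_tests(vals, groups) == pytest.approx(1.0)

    def test_chi_square_on_diagonal_table(self):
        vals = ["x"] * 10 + ["y"] * 10
        groups = ["a"] * 10 + ["b"] * 10
        assert group_tests(vals, groups, categorical=True) < 0.05

    def test_three_identical_groups_p_one(self):
        vals = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        assert group_tests(vals, groups) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1, 2], ["a", "a"])
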