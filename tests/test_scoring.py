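"""Unit tests for fold ratios, IRS/HRS, cutoff optimization and rescue."""

import numpy as np
import pandas as pd
import pytest

from insitro import scoring
from insitro.errors import ValidationError

from conftest import make_conc


def fr_for(tumor="T1", **analyte_pairs):
    """Concentration rows for one tumor: analyte -> (stim, ref) pairs."""
    rows = []
    for a, (stim, ref) in analyte_pairs.items():
        rows.append((tumor, "aPD1", a, stim, "in_range"))
        rows.append((tumor, "medium", a, ref, "in_range"))
    return make_conc(rows)


class TestFoldRatio:
    @pytest.mark.parametrize(
        "stim,ref,expected", [(100.0, 100.0, 1.0), (150.0, 100.0, 1.5), (40.0, 80.0, 0.5)]
    )
    def test_plain_division(self, stim, ref, expected):
        fr = scoring.fold_ratio_table(fr_for(a1=(stim, ref)), "aPD1", "medium")
        assert fr["fold_ratio"].iloc[0] == pytest.approx(expected)
        assert fr["policy_applied"].iloc[0] == "none"

    def test_half_lloq_substitution(self):
        # reference below LLOQ (stored as LLOQ=10) -> divide by 10/2 = 5
        conc = make_conc(
            [("T1", "aPD1", "a1", 40.0, "in_range"), ("T1", "medium", "a1", 10.0, "below_lloq")]
        )
        fr = scoring.fold_ratio_table(conc, "aPD1", "medium")
        assert fr["fold_ratio"].iloc[0] == pytest.approx(8.0)
        assert fr["policy_applied"].iloc[0] == "half_lloq_substitution"

    def test_both_below_lloq_missing(self):
        conc = make_conc(
            [("T1", "aPD1", "a1", 10.0, "below_lloq"), ("T1", "medium", "a1", 10.0, "below_lloq")]
        )
        fr = scoring.fold_ratio_table(conc, "aPD1", "medium")
        assert np.isnan(fr["fold_ratio"].iloc[0])
        assert fr["policy_applied"].iloc[0] == "undefined_missing"

    def test_missing_operand_propagates(self):
        conc = make_conc(
            [("T1", "aPD1", "a1", np.nan, "missing"), ("T1", "medium", "a1", 50.0, "in_range")]
        )
        fr = scoring.fold_ratio_table(conc, "aPD1", "medium")
        assert np.isnan(fr["fold_ratio"].iloc[0])
        assert fr["policy_applied"].iloc[0] == "undefined_missing"

    def test_identical_conditions_rejected(self):
        with pytest.raises(ValidationError):
            scoring.fold_ratio_table(fr_for(a1=(1, 1)), "medium", "medium")

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError, match="not present"):
            scoring.fold_ratio_table(fr_for(a1=(1, 1)), "aPD1", "isotype")


class TestSelection:
    def test_all_unity_selects_nothing(self):
        rows = [(f"T{t}", "aCD3_aCD28", a, 1.0, None) for t in range(4) for a in "abc"]
        fr = pd.DataFrame(
            rows, columns=["tumor_id", "condition", "analyte", "fold_ratio", "policy_applied"]
        )
        assert scoring.select_tcr_dependent(fr) == []

    def test_median_rule_on_toy_cohort(self):
        # per-analyte medians over 4 tumors: a1 -> 2.0, a2 -> 1.4, a3 -> 1.6
        vals = {"a1": [1.8, 2.2, 1.9, 2.1], "a2": [1.3, 1.5, 1.2, 1.6], "a3": [1.5, 1.7, 1.4, 1.8]}
        rows = [
            (f"T{t}", "aCD3_aCD28", a, v[t], None) for a, v in vals.items() for t in range(4)
        ]
        fr = pd.DataFrame(
            rows, columns=["tumor_id", "condition", "analyte", "fold_ratio", "policy_applied"]
        )
        assert scoring.select_tcr_dependent(fr, threshold=1.5) == ["a1", "a3"]

    def test_threshold_is_strict(self):
        rows = [(f"T{t}", "c", "a", 1.5, None) for t in range(3)]
        fr = pd.DataFrame(
            rows, columns=["tumor_id", "condition", "analyte", "fold_ratio", "policy_applied"]
        )
        assert scoring.select_tcr_dependent(fr, threshold=1.5) == []

    def test_single_tumor_warns_but_works(self):
        fr = pd.DataFrame(
            [("T1", "c", "a", 2.0, None)],
            columns=["tumor_id", "condition", "analyte", "fold_ratio", "policy_applied"],
        )
        with pytest.warns(UserWarning, match="unstable"):
            assert scoring.select_tcr_dependent(fr, min_tumors=1) == ["a"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            scoring.select_tcr_dependent(pd.DataFrame(columns=["tumor_id", "analyte", "fold_ratio", "condition"]))


PANEL = [f"sf{i}" for i in range(17)]


def row(n_positive, positive_value=2.0, negative_value=1.0):
    vals = [positive_value] * n_positive + [negative_value] * (17 - n_positive)
    return pd.Series(vals, index=PANEL)


class TestIRS:
    def test_seven_of_seventeen_is_positivity_threshold(self):
        res = scoring.immune_reactivity_score(row(7), PANEL)
        assert res.irs_percent == 41.18
        assert res.irs_label == "IRS_high"

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (17, 100.0), (6, 35.29)])
    def test_percent_transform(self, n, expected):
        assert scoring.immune_reactivity_score(row(n), PANEL).irs_percent == expected

    def test_boundary_value_counts_positive(self):
        res = scoring.immune_reactivity_score(row(7, positive_value=1.5), PANEL)
        assert res.n_positive == 7
        # strict_positivity flips the >= to >
        strict = scoring.immune_reactivity_score(
            row(7, positive_value=1.5), PANEL, strict_positivity=True
        )
        assert strict.n_positive == 0

    def test_missing_counts_non_positive_under_fixed_denominator(self):
        vals = row(7)
        vals.iloc[10:] = np.nan
        res = scoring.immune_reactivity_score(vals, PANEL)
        assert (res.n_positive, res.n_evaluable) == (7, 10)
        assert res.irs_percent == 41.18

    def test_evaluable_denominator_option(self):
        vals = row(7)
        vals.iloc[10:] = np.nan  # 10 evaluable, 7 positive
        res = scoring.immune_reactivity_score(vals, PANEL, denominator="evaluable")
        assert res.irs_percent == 70.0

    def test_nonstandard_panel_warns(self):
        with pytest.warns(UserWarning, match="panel"):
            res = scoring.immune_reactivity_score(
                pd.Series({"a": 2.0, "b": 1.0}), ["a", "b"]
            )
        assert res.irs_percent == 50.0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            scoring.immune_reactivity_score(row(0), [])

    def test_classification_equivalence_all_counts(self):
        # IRS >= 41.18 is exactly n_positive >= 7, over all 18 possible counts
        for n in range(18):
            res = scoring.immune_reactivity_score(row(n), PANEL)
            assert (res.irs_label == "IRS_high") == (n >= 7)


class TestHRS:
    def test_all_unity_scores_zero(self):
        full = pd.Series(1.0, index=[f"a{i}" for i in range(27)])
        assert scoring.hypo_responsive_score(full) == (0, 27)

    def test_all_suppressed_scores_27(self):
        full = pd.Series(0.01, index=[f"a{i}" for i in range(27)])
        assert scoring.hypo_responsive_score(full) == (27, 27)

    def test_six_suppressed_is_high_at_published_threshold(self):
        vals = pd.Series([0.05] * 6 + [1.0] * 21, index=[f"a{i}" for i in range(27)])
        hrs, _ = scoring.hypo_responsive_score(vals)
        assert hrs == 6
        assert scoring.classify_hrs(hrs, 5.5) == "HRS_high"

    def test_threshold_is_strictly_below(self):
        vals = pd.Series([0.1] * 27, index=[f"a{i}" for i in range(27)])
        assert scoring.hypo_responsive_score(vals)[0] == 0

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 2, 4, 6, 8, 10], 5.0),
            ([3, 5, 6, 7, 8, 9, 2, 4, 6, 7], 6.0),  # sorted middle pair (6+6)/2
        ],
    )
    def test_cohort_median_threshold(self, values, expected):
        assert scoring.hrs_threshold(values) == expected

    def test_all_equal_cohort_all_low_under_strict(self):
        thr = scoring.hrs_threshold([4, 4, 4, 4])
        assert thr == 4.0
        assert scoring.classify_hrs(4, thr, strict=True) == "HRS_low"
        assert scoring.classify_hrs(4, thr, strict=False) == "HRS_high"

    def test_single_tumor_rejected(self):
        with pytest.raises(ValidationError):
            scoring.hrs_threshold([3])


def brute_force_cutoff(scores, labels):
    """Independent exhaustive search mirroring the documented rule."""
    scores = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    pos, neg = scores[lab], scores[~lab]
    best = None
    for k in range(18):
        c = round(100.0 * k / 17, 2)
        tp = (pos >= c).sum()
        tn = (neg < c).sum()
        sens, spec = tp / len(pos), tn / len(neg)
        if spec == 1.0:
            lr = ((tp + 0.5) / (len(pos) + 1)) / (1 - (tn + 0.5) / (len(neg) + 1))
        else:
            lr = sens / (1 - spec)
        key = (lr, sens + spec - 1, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


class TestOptimizeCutoff:
    def test_perfect_separation(self):
        scores = [10, 20, 30, 50, 60, 70]
        labels = [False, False, False, True, True, True]
        res = scoring.optimize_cutoff(scores, labels)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        # smallest achievable candidate in the separating gap
        assert res.cutoff == brute_force_cutoff(scores, labels) == 35.29
        assert len(res.table) == 18

    def test_string_labels_accepted(self):
        res = scoring.optimize_cutoff(
            [10, 60], ["NR_clus", "R_clus"]
        )
        assert res.sensitivity == 1.0

    def test_uninformative_scores_flagged(self):
        res = scoring.optimize_cutoff([50, 50, 50, 50], [True, True, False, False])
        assert not res.informative

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            scoring.optimize_cutoff([1, 2, 3], [True, True, True])

    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            scores = np.round(100 * rng.integers(0, 18, size=n) / 17, 2)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = scoring.optimize_cutoff(scores, labels)
            assert res.cutoff == brute_force_cutoff(scores, labels)


class TestCombinationRescue:
    def scores_df(self, rows):
        return pd.DataFrame(rows, columns=["tumor_id", "condition", "irs_percent"])

    def test_rescued_tumor(self):
        df = self.scores_df(
            [("T1", "aPD1", 29.41), ("T1", "aPD1_TLR4ag", 52.94), ("T1", "aPD1_aCTLA4", 35.29)]
        )
        res = scoring.combination_rescue(df)
        t = res.per_tumor.loc["T1"]
        assert t["rescued"] and t["best_condition"] == "aPD1_TLR4ag"

    def test_high_alone_never_rescued(self):
        df = self.scores_df([("T1", "aPD1", 58.82), ("T1", "aPD1_TLR4ag", 100.0)])
        res = scoring.combination_rescue(df)
        assert not res.per_tumor.loc["T1", "rescued"]
        assert res.per_tumor.loc["T1", "irs_high_alone"]

    def test_untested_cells_stay_untested(self):
        df = self.scores_df(
            [("T1", "aPD1", 10.0), ("T1", "comboA", 20.0), ("T2", "aPD1", 10.0)]
        )
        res = scoring.combination_rescue(df)
        assert np.isnan(res.matrix.loc["T2", "comboA"])
        assert res.per_tumor.loc["T2", "n_combos_tested"] == 0
        assert not res.per_tumor.loc["T2", "rescued"]

    def test_missing_anti_pd1_excluded_with_warning(self):
        df = self.scores_df([("T1", "aPD1", 10.0), ("T2", "comboA", 90.0)])
        with pytest.warns(UserWarning, match="excluded"):
            res = scoring.combination_rescue(df)
        assert res.excluded_tumors == ["T2"]
        assert "T2" not in res.per_tumor.index

    def test_toy_cohort_enumeration(self):
        # 4 tumors x 3 combos, hand-set: T1 high alone, T2 rescued by B,
        # T3 rescued by A and C (best = higher IRS), T4 never rescued
        rows = [
            ("T1", "aPD1", 47.06), ("T1", "A", 52.94),
            ("T2", "aPD1", 23.53), ("T2", "A", 35.29), ("T2", "B", 41.18),
            ("T3", "aPD1", 11.76), ("T3", "A", 41.18), ("T3", "B", 17.65), ("T3", "C", 47.06),
            ("T4", "aPD1", 29.41), ("T4", "A", 35.29), ("T4", "B", 29.41), ("T4", "C", 5.88),
        ]
        res = scoring.combination_rescue(self.scores_df(rows))
        assert res.per_tumor["rescued"].tolist() == [False, True, True, False]
        assert res.per_tumor.loc["T3", "best_condition"] == "C"
        assert int(res.per_tumor["rescued"].sum()) == 2

    def test_tie_broken_by_condition_order(self):
        rows = [("T1", "aPD1", 10.0), ("T1", "B", 50.0), ("T1", "A", 50.0)]
        res = scoring.combination_rescue(self.scores_df(rows))
        assert res.per_tumor.loc["T1", "best_condition"] == "A"  # sorted order
        res2 = scoring.combination_rescue(
            self.scores_df(rows), condition_order=["B", "A"]
        )
        assert res2.per_tumor.loc["T1", "best_condition"] == "B"
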