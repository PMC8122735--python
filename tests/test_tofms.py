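"""GC-TOF-MS branch: reject filter, aggregation, chemical testing."""

import numpy as np
import pandas as pd
import pytest

from conftest import ranksum_p_by_enumeration
from vocdx.crossval import CVConfig
from vocdx.tofms import (
    RejectSettings,
    aggregate_chemicals,
    chemical_report,
    classify_chemical_features,
    count_peaks,
    filter_peaks,
    significant_chemicals,
)
from vocdx.tofms import test_chemicals as run_chemical_tests


def peak_row(sample="s1", chemical="c1", rt=2.0, height=20000.0, width=0.05, area=20000.0):
    return {
        "sample_id": sample, "chemical": chemical, "retention_time_min": rt,
        "height": height, "width": width, "area": area,
    }


class TestFilterPeaks:
    def test_height_just_below_reject_removed(self):
        t = pd.DataFrame([peak_row(height=9_999.0)])
        assert len(filter_peaks(t)) == 0

    def test_exact_boundary_retained(self):
        t = pd.DataFrame([peak_row(height=10_000.0, area=10_000.0, width=0.01)])
        assert len(filter_peaks(t)) == 1

    def test_hand_counted_toy_table(self):
        rows = [
            peak_row("a", "c1", height=50_000, area=50_000, width=0.05),   # keep
            peak_row("a", "c2", height=9_000, area=50_000, width=0.05),    # height fails
            peak_row("a", "c3", height=50_000, area=8_000, width=0.05),    # area fails
            peak_row("a", "c4", height=50_000, area=50_000, width=0.005),  # width fails
            peak_row("a", "c5", height=10_000, area=10_000, width=0.01),   # boundary keep
        ]
        out = filter_peaks(pd.DataFrame(rows))
        assert list(out["chemical"]) == ["c1", "c5"]

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        rows = [
            peak_row("a", f"c{i}", height=float(h), area=float(h) * 0.6, width=0.05)
            for i, h in enumerate(rng.uniform(5_000, 60_000, 30))
        ]
        t = pd.DataFrame(rows)
        once = filter_peaks(t)
        twice = filter_peaks(once)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)

    def test_anti_monotone_in_each_reject(self):
        rng = np.random.default_rng(1)
        rows = [
            peak_row("a", f"c{i}", height=float(h), area=float(a), width=float(w))
            for i, (h, a, w) in enumerate(
                zip(
                    rng.uniform(1_000, 80_000, 50),
                    rng.uniform(1_000, 80_000, 50),
                    rng.uniform(0.001, 0.2, 50),
                )
            )
        ]
        t = pd.DataFrame(rows)
        base = len(filter_peaks(t, RejectSettings()))
        for kwargs in (
            {"height_reject": 20_000.0},
            {"area_reject": 20_000.0},
            {"width_reject": 0.05},
        ):
            assert len(filter_peaks(t, RejectSettings(**kwargs))) <= base

    def test_empty_table_passes_through(self):
        t = pd.DataFrame(columns=["sample_id", "chemical", "retention_time_min", "height", "width", "area"])
        assert len(filter_peaks(t)) == 0


class TestAggregateChemicals:
    def test_one_peak_per_cell(self):
        t = pd.DataFrame([peak_row("a", "c1", area=100.0), peak_row("a", "c2", area=200.0)])
        abundance, rep_rt = aggregate_chemicals(t)
        assert abundance.loc["a", "c1"] == 100.0
        assert abundance.loc["a", "c2"] == 200.0
        assert rep_rt["c1"] == 2.0

    def test_absent_chemical_is_zero(self):
        t = pd.DataFrame([peak_row("a", "c1"), peak_row("b", "c2")])
        abundance, _ = aggregate_chemicals(t)
        assert abundance.loc["a", "c2"] == 0.0
        assert abundance.loc["b", "c1"] == 0.0

    def test_duplicate_rows_summed(self):
        t = pd.DataFrame([peak_row("a", "c1", area=100.0), peak_row("a", "c1", area=50.0)])
        abundance, _ = aggregate_chemicals(t)
        assert abundance.loc["a", "c1"] == 150.0

    def test_labels_add_peakless_samples(self):
        t = pd.DataFrame([peak_row("a", "c1")])
        labels = pd.DataFrame({"sample_id": ["a", "b"], "group": ["HCC", "fibrosis"]})
        abundance, _ = aggregate_chemicals(t, labels)
        assert abundance.loc["b", "c1"] == 0.0


def _abundance_frame(case_vals, control_vals, chemical="c1"):
    ids = [f"p{i}" for i in range(len(case_vals))] + [f"q{i}" for i in range(len(control_vals))]
    df = pd.DataFrame({chemical: list(case_vals) + list(control_vals)}, index=ids)
    df.index.name = "sample_id"
    groups = pd.Series(
        ["HCC"] * len(case_vals) + ["fibrosis"] * len(control_vals), index=ids
    )
    return df, groups


class TestTestChemicals:
    def test_identical_distributions_give_p_one(self):
        df, groups = _abundance_frame([5.0] * 4, [5.0] * 4)
        res = run_chemical_tests(df, groups, "HCC")[0]
        assert res.p_value == 1.0
        assert res.direction == "undetermined"

    def test_case_above_control_is_higher(self):
        df, groups = _abundance_frame([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        res = run_chemical_tests(df, groups, "HCC")[0]
        assert res.direction == "higher"
        assert res.p_value < 0.2

    def test_small_n_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        case = rng.normal(1.0, 1.0, 4)
        control = rng.normal(0.0, 1.0, 4)
        df, groups = _abundance_frame(case, control)
        res = run_chemical_tests(df, groups, "HCC")[0]
        assert res.p_value == pytest.approx(ranksum_p_by_enumeration(case, control), rel=1e-9)

    def test_pvalue_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        case = rng.lognormal(1.0, 0.5, 8)
        control = rng.lognormal(0.0, 0.5, 10)
        df1, groups = _abundance_frame(case, control)
        df2, _ = _abundance_frame(np.log(case), np.log(control))
        p1 = run_chemical_tests(df1, groups, "HCC")[0].p_value
        p2 = run_chemical_tests(df2, groups, "HCC")[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_empty_group_rejected(self):
        df, groups = _abundance_frame([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            run_chemical_tests(df, groups, "nonexistent-group")


class TestSignificantChemicals:
    def test_strict_inequality_at_alpha(self):
        df, groups = _abundance_frame([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        results = run_chemical_tests(df, groups, "HCC")
        results[0].p_value = 0.04
        r2 = [results[0]]
        for p in (0.05, 0.06):
            import copy

            r = copy.deepcopy(results[0])
            r.p_value = p
            r2.append(r)
        assert len(significant_chemicals(r2, alpha=0.05)) == 1

    def test_empty_input(self):
        assert significant_chemicals([]) == []

    def test_report_table_shape(self):
        df, groups = _abundance_frame([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        results = run_chemical_tests(df, groups, "HCC")
        table = chemical_report(results, case_group="HCC")
        assert list(table.columns) == [
            "No.", "RetentionTime(min)", "Chemical", "p-value", "Abundance Change",
        ]
        assert table.loc[0, "Abundance Change"] == "Higher for HCC"


class TestClassifyChemicalFeatures:
    def test_feature_selection_bypassed(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            rng.uniform(size=(20, 6)), columns=[f"c{i}" for i in range(6)],
            index=[f"s{i}" for i in range(20)],
        )
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        res = classify_chemical_features(df, y, CVConfig(n_folds=5, classifier="linear_regression"))
        for selected in res.selected_features.values():
            assert sorted(selected) == list(range(6))

    def test_planted_separable_chemical_reaches_high_auc(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 10))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X[y == 1, 0] += 3.0
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(10)], index=[f"s{i}" for i in range(40)])
        res = classify_chemical_features(df, y, CVConfig(classifier="logistic_regression", seed=1))
        assert res.auc() >= 0.9


class TestCountPeaks:
    def test_uniform_counts(self):
        rows = [peak_row(s, f"c{i}") for s in ("a", "b") for i in range(10)]
        groups = pd.Series({"a": "HCC", "b": "fibrosis"})
        assert count_peaks(pd.DataFrame(rows), groups, ("HCC", "fibrosis")) == 10

    def test_empty_table(self):
        t = pd.DataFrame(columns=["sample_id", "chemical", "retention_time_min", "height", "width", "area"])
        groups = pd.Series({"a": "HCC"})
        assert count_peaks(t, groups, ("HCC", "fibrosis")) == 0

    def test_mean_of_two_samples(self):
        rows = [peak_row("a", f"c{i}") for i in range(5)] + [
            peak_row("b", f"c{i}") for i in range(7)
        ]
        groups = pd.Series({"a": "HCC", "b": "fibrosis"})
        assert count_peaks(pd.DataFrame(rows), groups, ("HCC", "fibrosis")) == 6

    def test_samples_outside_comparison_excluded(self):
        rows = [peak_row("a", f"c{i}") for i in range(4)] + [
            peak_row("c", f"c{i}") for i in range(20)
        ]
        groups = pd.Series({"a": "HCC", "b": "fibrosis", "c": "non-fibrosis"})
        # sample b has zero peaks and counts as 0; c is outside the comparison
        assert count_peaks(pd.DataFrame(rows), groups, ("HCC", "fibrosis")) == 2
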