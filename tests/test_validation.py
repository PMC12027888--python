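import numpy as np
import pandas as pd
import pytest

from qusrad.validation import (
    ConfusionCounts,
    cohort_summary,
    confusion,
    fixture_path,
    load_cohort,
    metrics,
    recist_change,
    validate_report,
)


class TestLoader:
    def test_fixture_loads_56_records(self, cohort_df):
        assert len(cohort_df) == 56
        assert cohort_df["treatment_changed"].sum() == 3
        assert sorted(cohort_df.loc[cohort_df["treatment_changed"], "id"]) == [19, 21, 53]

    def test_first_patient_row(self, cohort_df):
        row = cohort_df.set_index("id").loc[1]
        assert row["pre_nac_size_cm"] == 3.0
        assert row["post_nac_size_cm"] == 2.7
        assert row["actual_response"] == "NR"
        assert row["predicted_response"] == "NR"

    def test_rcb_markers_kept_typed(self, cohort_df):
        rcb = cohort_df.set_index("id")["rcb"]
        assert rcb.loc[36] == "pCR"
        assert rcb.loc[21] is None or pd.isna(rcb.loc[21])
        assert rcb.loc[1] == "2.24"  # stored value, never coerced

    def test_truncated_file_names_missing_ids(self, tmp_path, cohort_df):
        truncated = tmp_path / "short.csv"
        pd.read_csv(fixture_path()).iloc[:50].to_csv(truncated, index=False)
        with pytest.raises(ValueError, match=r"missing ids \[51, 52, 53, 54, 55, 56\]"):
            load_cohort(str(truncated))

    def test_duplicate_id_rejected(self, tmp_path):
        df = pd.read_csv(fixture_path())
        df.loc[1, "id"] = 1
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_cohort(str(path))

    def test_missing_column_rejected(self, tmp_path):
        df = pd.read_csv(fixture_path()).drop(columns=["actual_response"])
        path = tmp_path / "cols.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            load_cohort(str(path))


class TestConfusion:
    def test_full_cohort_counts(self, cohort_df):
        c = confusion(cohort_df)
        assert (c.TP, c.FP, c.FN, c.TN) == (47, 2, 3, 4)
        assert c.total == 56

    def test_exclusion_removes_flagged_rows_only(self, cohort_df):
        c = confusion(cohort_df, exclude_changed=True)
        assert (c.TP, c.FP, c.FN, c.TN) == (47, 0, 3, 3)
        assert c.total == 53

    def test_order_invariance(self, cohort_df):
        shuffled = cohort_df.sample(frac=1.0, random_state=0)
        assert confusion(shuffled) == confusion(cohort_df)


class TestMetrics:
    def test_full_cohort_metric_set(self):
        m = metrics(ConfusionCounts(47, 2, 3, 4))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f1) == (94, 67, 96, 57, 95)

    def test_exclusion_metric_set(self):
        m = metrics(ConfusionCounts(47, 0, 3, 3))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f1) == (94, 100, 100, 50, 97)

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(30, 0, 0, 10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.f1, m.accuracy) == (
            100, 100, 100, 100, 100, 100,
        )

    def test_zero_denominator_flagged_undefined(self):
        m = metrics(ConfusionCounts(10, 0, 0, 0))
        assert m.specificity is None and m.npv is None
        assert m.sensitivity == 100 and m.f1 == 100

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        m = metrics(ConfusionCounts(47, 2, 3, 4))
        ppv, sens = m.raw["ppv"], m.raw["sensitivity"]
        assert m.raw["f1"] == pytest.approx(2 * ppv * sens / (ppv + sens))

    def test_rounding_half_away_from_zero(self):
        # 57.142 -> 57, 96.9 -> 97, 94.949 -> 95, and .5 rounds up
        m = metrics(ConfusionCounts(1, 1, 1, 1))
        assert m.sensitivity == 50
        assert metrics(ConfusionCounts(5, 3, 3, 5)).sensitivity == 63  # 62.5 up


class TestRecist:
    def test_patient1_small_decrease_is_nonresponse(self):
        out = recist_change(3.0, 2.7)
        assert out["percent_change"] == pytest.approx(10.0)
        assert out["category"] == "non-response"

    def test_patient4_over_30pct_is_response(self):
        out = recist_change(1.9, 1.3)
        assert out["percent_change"] == pytest.approx(31.578947368)
        assert out["category"] == "response"

    def test_no_change_is_nonresponse(self):
        assert recist_change(4.0, 4.0)["category"] == "non-response"

    def test_scale_invariance(self):
        for k in (0.1, 1.0, 2.5, 17.0):
            a = recist_change(3.0, 1.8)["percent_change"]
            b = recist_change(3.0 * k, 1.8 * k)["percent_change"]
            assert a == pytest.approx(b)

    def test_zero_pre_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            recist_change(0.0, 1.0)


class TestSummary:
    def test_fixture_medians_and_response_rate(self, cohort_df):
        s = cohort_summary(cohort_df)
        assert s["median_age"] == 50.0
        assert s["response_rate"] == 89.3
        assert s["median_pre_size"] == pytest.approx(3.65)

    def test_single_record(self, cohort_df):
        s = cohort_summary(cohort_df.iloc[[0]])
        assert s["median_age"] == 47.0
        assert s["median_pre_size"] == 3.0


def test_report_structure(cohort_df):
    report = validate_report(cohort_df)
    assert report["counts"] == {"TP": 47, "FP": 2, "FN": 3, "TN": 4}
    assert report["metrics"]["f1"] == 95
    report_x = validate_report(cohort_df, exclude_changed=True)
    assert report_x["counts"]["FP"] == 0
    assert report_x["summary"]["n"] == 53
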