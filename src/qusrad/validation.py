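"""Clinical validation arithmetic for the 56-patient cohort.

Loads the packaged per-patient table (covariates, pre/post-treatment tumour
sizes, receptor status, actual and model-predicted response), builds
confusion-matrix counts with the responder as the positive class, and
computes sensitivity, specificity, PPV, NPV, F1 and accuracy as integer
percentages (half away from zero — the rounding that reproduces every
printed value).  Three patients had an unplanned change of chemotherapy
after the prediction was disclosed; metrics are available with and without
them.  A RECIST-style size-change classifier (≥ 30% diameter decrease =
response) is provided as an advisory check only: the cohort's actual labels
combine clinical and pathological assessment and are taken from the table
as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ValidationMetrics",
    "fixture_path",
    "load_cohort",
    "confusion",
    "metrics",
    "recist_change",
    "cohort_summary",
    "validate_report",
]

REQUIRED_COLUMNS = [
    "id",
    "age",
    "er",
    "pr",
    "her2",
    "histology",
    "grade",
    "pre_nac_size_cm",
    "pre_t_stage",
    "pre_n_stage",
    "treatment",
    "treatment_changed",
    "post_nac_size_cm",
    "cellularity_pct",
    "rcb",
    "actual_response",
    "predicted_response",
]

RESPONSE_THRESHOLD_PCT = 30.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts with responder (R) as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class ValidationMetrics:
    """Rounded integer-percent metrics plus full-precision values.

    ``None`` marks a metric whose denominator is zero (undefined).
    """

    sensitivity: int | None
    specificity: int | None
    ppv: int | None
    npv: int | None
    f1: int | None
    accuracy: int | None
    raw: dict[str, float | None]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fixture_path() -> str:
    """Path of the packaged 56-patient validation table."""
    return str(resources.files("qusrad.data") / "validation_cohort.csv")


def load_cohort(path: str | None = None, expected_count: int | None = 56) -> pd.DataFrame:
    """Load and validate the per-patient cohort table.

    Checks the schema (columns, unique complete ids, parseable values,
    non-missing response labels, non-negative sizes) and reports offending
    rows.  ``expected_count=None`` skips the completeness check for
    non-standard cohorts.
    """
    if path is None:
        path = fixture_path()
    df = pd.read_csv(path, dtype={"er": str, "pr": str, "her2": str, "rcb": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")

    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].tolist())
        raise ValueError(f"duplicate patient ids: {dupes}")
    if expected_count is not None:
        expected = set(range(1, expected_count + 1))
        missing_ids = sorted(expected - set(df["id"]))
        if missing_ids or len(df) != expected_count:
            raise ValueError(
                f"expected patients 1-{expected_count}; missing ids {missing_ids}"
            )

    bad = df.index[~df["actual_response"].isin(["R", "NR"])].tolist()
    bad += df.index[~df["predicted_response"].isin(["R", "NR"])].tolist()
    if bad:
        raise ValueError(f"unparseable response labels at rows {sorted(set(bad))}")
    for col in ("er", "pr", "her2"):
        bad = df.index[~df[col].isin(["+", "-"])].tolist()
        if bad:
            raise ValueError(f"unparseable {col} status at rows {bad}")
    for col in ("pre_nac_size_cm", "post_nac_size_cm"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | (values < 0)].tolist()
        if bad:
            raise ValueError(f"invalid {col} at rows {bad}")
        df[col] = values
    df["treatment_changed"] = df["treatment_changed"].astype(bool)
    # RCB kept as typed markers: float score, 'pCR', or missing (never coerced)
    df["rcb"] = df["rcb"].where(df["rcb"].notna(), None)
    return df


def confusion(records: pd.DataFrame, exclude_changed: bool = False) -> ConfusionCounts:
    """Confusion counts of predicted vs actual response.

    ``exclude_changed`` removes patients whose chemotherapy was changed
    after the prediction was disclosed.
    """
    df = records
    if exclude_changed:
        df = df.loc[~df["treatment_changed"]]
    if len(df) == 0:
        raise ValueError("no records left after exclusion")
    actual = df["actual_response"] == "R"
    predicted = df["predicted_response"] == "R"
    return ConfusionCounts(
        TP=int((actual & predicted).sum()),
        FP=int((~actual & predicted).sum()),
        FN=int((actual & ~predicted).sum()),
        TN=int((~actual & ~predicted).sum()),
    )


def _safe_ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> ValidationMetrics:
    """Diagnostic-accuracy metrics as integer percentages.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), F1 = 2TP/(2TP+FP+FN), accuracy = (TP+TN)/total, each
    ×100 and rounded half away from zero.  Zero-denominator metrics are
    returned as None with the others intact.
    """
    raw = {
        "sensitivity": _safe_ratio(counts.TP, counts.TP + counts.FN),
        "specificity": _safe_ratio(counts.TN, counts.TN + counts.FP),
        "ppv": _safe_ratio(counts.TP, counts.TP + counts.FP),
        "npv": _safe_ratio(counts.TN, counts.TN + counts.FN),
        "f1": _safe_ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN),
        "accuracy": _safe_ratio(counts.TP + counts.TN, counts.total),
    }
    rounded = {
        k: (_round_half_away(v) if v is not None else None) for k, v in raw.items()
    }
    return ValidationMetrics(**rounded, raw=raw)


def recist_change(pre_size: float, post_size: float) -> dict[str, object]:
    """Percent diameter change and RECIST-style response category.

    Response requires at least a 30% decrease in the target-lesion
    diameter; anything less (including growth) is non-response.
    """
    if pre_size <= 0:
        raise ValueError("pre-treatment size must be positive")
    if post_size < 0:
        raise ValueError("post-treatment size must be non-negative")
    percent_change = (pre_size - post_size) / pre_size * 100.0
    category = "response" if percent_change >= RESPONSE_THRESHOLD_PCT else "non-response"
    return {"percent_change": percent_change, "category": category}


def _subtype_of_row(row: pd.Series) -> str:
    from .features import molecular_subtype

    return molecular_subtype(row["er"], row["pr"], row["her2"]).value


def _regimen_family(treatment: str) -> str:
    t = treatment.lower()
    if t.startswith("ac") and "paclitaxel" in t:
        return "AC-paclitaxel"
    if "fec" in t:
        return "FEC-docetaxel"
    return "taxane-other"


def cohort_summary(records: pd.DataFrame) -> dict[str, object]:
    """Cohort descriptives: medians, response rate, subtype and regimen mix.

    Medians use the standard even-n convention (mean of the two central
    order statistics); proportions are rounded to one decimal percent.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    response_rate = 100.0 * (records["actual_response"] == "R").mean()
    subtype = records.apply(_subtype_of_row, axis=1).value_counts(normalize=True)
    regimen = records["treatment"].map(_regimen_family).value_counts(normalize=True)
    return {
        "n": int(len(records)),
        "median_age": float(records["age"].median()),
        "median_pre_size": float(records["pre_nac_size_cm"].median()),
        "response_rate": float(round(response_rate, 1)),
        "subtype_fractions": {k: round(100.0 * v, 1) for k, v in subtype.items()},
        "regimen_fractions": {k: round(100.0 * v, 1) for k, v in regimen.items()},
    }


def validate_report(
    records: pd.DataFrame, exclude_changed: bool = False
) -> dict[str, object]:
    """Counts, full-precision and rounded metrics, and the summary block."""
    counts = confusion(records, exclude_changed=exclude_changed)
    m = metrics(counts)
    return {
        "exclude_changed": exclude_changed,
        "counts": {"TP": counts.TP, "FP": counts.FP, "FN": counts.FN, "TN": counts.TN},
        "metrics": {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
            "npv": m.npv,
            "f1": m.f1,
            "accuracy": m.accuracy,
        },
        "metrics_full_precision": m.raw,
        "summary": cohort_summary(
            records.loc[~records["treatment_changed"]] if exclude_changed else records
        ),
    }
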