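"""SVM-RBF response classification with sequential forward feature selection.

The classifier predicts neoadjuvant-chemotherapy response (R vs NR) from the
QUS/texture-derivative feature table plus one-hot molecular subtype.
Selection is greedy forward search maximizing cross-validated balanced
accuracy; the final model is a grid-searched RBF SVM with Platt probability
calibration on z-scored selected features.  Predictions carry a label, a
signed class score in [−1, 1] (2·P(R) − 1, positive for predicted
responders) and the signed decision-function value as the hyperplane
distance.  A decision value of exactly 0 ties conservatively to NR, so a
borderline case is flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import MolecularSubtype

__all__ = [
    "ModelConfig",
    "Prediction",
    "TrainedModel",
    "encode_subtypes",
    "select_features",
    "train",
    "predict",
    "save_model",
    "load_model",
]

LABELS = ("NR", "R")  # alphabetical; decision function positive => R


@dataclass(frozen=True)
class ModelConfig:
    n_selected_features: int = 10
    cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = tuple(np.logspace(-3, 1, 9))
    cv_folds: int = 5
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selected_features < 1:
            raise ValueError("n_selected_features must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class Prediction:
    tumour_id: str
    label: str
    class_score: float
    hp_distance: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if abs(self.class_score) > 1.0 + 1e-9:
            raise ValueError("class_score must lie in [-1, 1]")


@dataclass
class TrainedModel:
    """Fitted decision pipeline plus a Platt-calibrated copy.

    ``pipeline`` (scaler + SVC) provides labels and the signed hyperplane
    distance; ``calibrated`` (cross-validated sigmoid calibration of the
    same pipeline) provides the probability behind the class score.
    """

    pipeline: Pipeline
    calibrated: CalibratedClassifierCV
    selected_features: list[str]
    config: ModelConfig
    grid_search: dict = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)


def encode_subtypes(subtypes: pd.Series) -> pd.DataFrame:
    """One-hot encode molecular subtype with a fixed column order."""
    cats = [s.value for s in MolecularSubtype]
    frame = pd.DataFrame(
        0.0, index=subtypes.index, columns=[f"subtype-{c}" for c in cats]
    )
    for idx, value in subtypes.items():
        value = value.value if isinstance(value, MolecularSubtype) else str(value)
        if value not in cats:
            raise ValueError(f"unknown subtype {value!r}")
        frame.loc[idx, f"subtype-{value}"] = 1.0
    return frame


def _impute(X: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing features (column mean; 0 if a column is all-NaN)."""
    X = X.copy()
    means = X.mean()
    return X.fillna(means.fillna(0.0))


def _cv(config: ModelConfig) -> StratifiedKFold:
    return StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )


def _base_pipeline(config: ModelConfig, C: float = 1.0, gamma="scale") -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel="rbf",
                    C=C,
                    gamma=gamma,
                    class_weight="balanced" if config.class_weighting else None,
                ),
            ),
        ]
    )


def select_features(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: ModelConfig | None = None
) -> list[str]:
    """Greedy sequential forward selection on CV balanced accuracy.

    At each step every remaining feature is scored by the cross-validated
    balanced accuracy of an RBF SVM on the candidate set; the best is kept
    (ties break to the earlier column, so the result is deterministic under
    a fixed seed and column order).
    """
    if config is None:
        config = ModelConfig()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("feature selection needs samples from two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    X = _impute(X)
    n_select = min(config.n_selected_features, X.shape[1])
    folds = list(_cv(config).split(np.zeros(len(y)), y))
    values = X.to_numpy()
    columns = list(X.columns)

    weighting = "balanced" if config.class_weighting else None

    def fold_score(col_idx: list[int]) -> float:
        scores = []
        for train_idx, test_idx in folds:
            Xtr = values[np.ix_(train_idx, col_idx)]
            Xte = values[np.ix_(test_idx, col_idx)]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            svc = SVC(kernel="rbf", class_weight=weighting)
            svc.fit((Xtr - mu) / sd, y[train_idx])
            pred = svc.predict((Xte - mu) / sd)
            scores.append(balanced_accuracy_score(y[test_idx], pred))
        return float(np.mean(scores))

    selected_idx: list[int] = []
    remaining = list(range(len(columns)))
    for _ in range(n_select):
        best_i, best_score = None, -np.inf
        for i in remaining:
            score = fold_score(selected_idx + [i])
            if score > best_score + 1e-12:
                best_i, best_score = i, score
        selected_idx.append(best_i)
        remaining.remove(best_i)
    return [columns[i] for i in selected_idx]


def train(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    selected: list[str] | None = None,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Grid-searched, probability-calibrated RBF SVM on selected features."""
    if config is None:
        config = ModelConfig()
    if selected is None:
        selected = list(X.columns)
    missing = [c for c in selected if c not in X.columns]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    y = np.asarray(y).astype(str)
    if set(np.unique(y)) - set(LABELS):
        raise ValueError(f"labels must be in {LABELS}")

    X = _impute(X[selected])
    variances = X.var(ddof=0)
    dropped = list(variances.index[variances == 0.0])
    keep = [c for c in selected if c not in dropped]
    if dropped:
        import warnings

        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("all selected features are degenerate")

    search = GridSearchCV(
        _base_pipeline(config),
        {"svc__C": list(config.cost_grid), "svc__gamma": list(config.gamma_grid)},
        cv=_cv(config),
        scoring="balanced_accuracy",
        refit=True,
    )
    features = X[keep].to_numpy()
    search.fit(features, y)
    record = {
        "best_params": {k: float(v) for k, v in search.best_params_.items()},
        "best_score": float(search.best_score_),
    }
    calibrated = CalibratedClassifierCV(
        clone(search.best_estimator_), method="sigmoid", cv=_cv(config), ensemble=False
    )
    calibrated.fit(features, y)
    return TrainedModel(
        pipeline=search.best_estimator_,
        calibrated=calibrated,
        selected_features=keep,
        config=config,
        grid_search=record,
        dropped_features=dropped,
    )


def _feature_row(model: TrainedModel, x) -> np.ndarray:
    if isinstance(x, pd.Series):
        values = x
    elif hasattr(x, "to_series"):
        values = x.to_series()
        if x.subtype is not None:
            sub = encode_subtypes(pd.Series([x.subtype], index=[0])).iloc[0]
            values = pd.concat([values, sub])
    else:
        values = pd.Series(x)
    missing = [f for f in model.selected_features if f not in values.index]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    row = values[model.selected_features].astype(float).to_numpy()
    if not np.all(np.isfinite(row)):
        raise ValueError("selected features contain non-finite values")
    return row.reshape(1, -1)


def predict(model: TrainedModel, x, tumour_id: str | None = None) -> Prediction:
    """Label, class score and hyperplane distance for one feature vector.

    The class score is 2·P(R) − 1 from Platt calibration; the hyperplane
    distance is the raw decision-function value.  Both are positive for
    predicted responders; a decision value of exactly 0 ties to NR.
    """
    row = _feature_row(model, x)
    decision = float(model.pipeline.decision_function(row)[0])
    proba = model.calibrated.predict_proba(row)[0]
    p_r = float(proba[list(model.calibrated.classes_).index("R")])
    label = "R" if decision > 0 else "NR"
    score = 2.0 * p_r - 1.0
    # Platt calibration can disagree in sign with the margin on borderline
    # cases; the score's sign follows the label, its magnitude the calibration.
    if decision != 0:
        score = abs(score) if decision > 0 else -abs(score)
    if tumour_id is None:
        tumour_id = getattr(x, "tumour_id", getattr(x, "name", "sample")) or "sample"
    return Prediction(
        tumour_id=str(tumour_id),
        label=label,
        class_score=score,
        hp_distance=decision,
    )


def save_model(model: TrainedModel, path: str) -> None:
    joblib.dump(
        {
            "pipeline": model.pipeline,
            "calibrated": model.calibrated,
            "selected_features": model.selected_features,
            "config": model.config,
            "grid_search": model.grid_search,
            "dropped_features": model.dropped_features,
        },
        path,
    )


def load_model(path: str) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(**payload)
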