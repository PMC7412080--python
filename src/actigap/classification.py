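"""Activity classifiers (SVM-RBF and 500-tree random forest) and CV splitters.

The two classifier families are standard: a support vector machine with an
RBF kernel (features standardized with training-set statistics only) and a
Breiman random forest with 500 trees and ``sqrt(n_features)`` candidate
features per split. Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns

MODEL_KINDS = ("svm_rbf", "random_forest")

CASES = ("clean_clean", "clean_missing", "missing_missing")


@dataclass(frozen=True)
class ModelConfig:
    """Classifier family and hyperparameters.

    ``rbf_gamma="scale"`` is 1 / (n_features * feature variance); C defaults
    to 1. The random forest uses ``n_trees`` trees (default 500).
    """

    kind: str = "random_forest"
    n_trees: int = 500
    rbf_gamma: float | str = "scale"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected {MODEL_KINDS}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class Model:
    """A fitted classifier plus the feature schema it was trained on."""

    estimator: object
    feature_names: tuple[str, ...]
    classes: tuple
    config: ModelConfig

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(table, self.feature_names)
        return self.estimator.predict(X)


@dataclass
class ScenarioResult:
    """Accuracy and per-class breakdown for one evaluation cell."""

    accuracy: float
    confusion: pd.DataFrame
    classifier: str
    n_windows: int
    case: str | None = None
    missing_rate: float | None = None
    window_s: float | None = None
    slide_s: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must be in [0, 1]")


def _design_matrix(table: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing_cols = [c for c in names if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns {missing_cols}")
    X = table[list(names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "feature table contains undefined entries; apply a fill policy first"
        )
    return X


def _build_estimator(config: ModelConfig):
    if config.kind == "svm_rbf":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=config.svm_c, gamma=config.rbf_gamma,
                random_state=config.seed),
        )
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        random_state=config.seed,
    )


def train(features: pd.DataFrame, config: ModelConfig) -> Model:
    """Fit the configured classifier on a filled feature table.

    Requires at least two classes and no undefined (NaN) feature entries.
    """
    names = tuple(feature_columns(features))
    y = features["label"].to_numpy()
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError(f"training needs >= 2 classes, got {classes}")
    X = _design_matrix(features, names)
    est = _build_estimator(config)
    est.fit(X, y)
    return Model(estimator=est, feature_names=names, classes=classes, config=config)


def evaluate(model: Model, features: pd.DataFrame) -> ScenarioResult:
    """Window-level accuracy and confusion matrix on a feature table."""
    y_true = features["label"].to_numpy()
    y_pred = model.predict(features)
    accuracy = float(np.mean(y_true == y_pred)) if len(y_true) else 0.0
    confusion = pd.crosstab(
        pd.Series(y_true, name="true"), pd.Series(y_pred, name="predicted"), dropna=False
    )
    return ScenarioResult(
        accuracy=accuracy,
        confusion=confusion,
        classifier=model.config.kind,
        n_windows=len(y_true),
        seed=model.config.seed,
    )


def stratified_window_splits(
    features: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified window-level split: (train row index, test row index).

    An alternative to leave-one-person-out for datasets without a canonical
    per-subject protocol; windows of the same recording may fall on both
    sides, so this measures within-distribution accuracy only.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for _, group in features.groupby("label"):
        n_test = max(1, int(round(test_fraction * len(group))))
        test_idx.extend(rng.choice(group.index.to_numpy(), size=n_test, replace=False))
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = features.index.difference(test_idx).to_numpy()
    return train_idx, test_idx


def leave_one_person_out_splits(
    features: pd.DataFrame,
) -> list[tuple[tuple, object]]:
    """One fold per subject: (train subject ids, held-out subject id).

    Folds partition the subjects; no subject appears on both sides of a fold.
    """
    if "subject" not in features.columns or features["subject"].isna().any():
        raise ValueError("feature table must carry subject ids for LOPO splits")
    subjects = sorted(pd.unique(features["subject"]))
    return [
        (tuple(s for s in subjects if s != held_out), held_out) for held_out in subjects
    ]
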