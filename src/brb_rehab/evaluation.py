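"""Scoring assessors on labelled cohorts and comparing against baselines.

`evaluate` scores a rule base (grade accuracy, utility MSE, confusion
counts).  `compare` runs any number of named assessors over the same data;
baselines wrap established classifiers (a feed-forward neural network and a
support-vector classifier from scikit-learn) behind the same
predict-grades interface, so the belief-rule-base model can be benchmarked
without re-implementing either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .core import BeliefRuleBase, assess_batch
from .simulate import LabelledDataset

__all__ = [
    "EvaluationReport",
    "GradePredictor",
    "BRBAssessor",
    "SklearnGradeAdapter",
    "neural_network_baseline",
    "svm_baseline",
    "majority_class_baseline",
    "evaluate",
    "evaluate_predictions",
    "compare",
    "comparison_table",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy, utility MSE and the confusion matrix behind them.

    ``confusion[t, p]`` counts records with true grade t+1 predicted as
    grade p+1; accuracy equals the trace over the total.
    """

    accuracy: float
    mse: float
    confusion: np.ndarray
    n_records: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mse": self.mse,
            "confusion": self.confusion.tolist(),
            "n_records": self.n_records,
        }


class GradePredictor(Protocol):
    """Anything that maps a feature matrix to 1-based grade predictions."""

    def predict_grades(self, features: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class BRBAssessor:
    """The belief-rule-base model behind the generic predictor interface."""

    brb: BeliefRuleBase
    renormalize: bool = False

    def predict_grades(self, features: np.ndarray) -> np.ndarray:
        _, _, grades = assess_batch(features, self.brb, renormalize=self.renormalize)
        return grades

    def predict_utilities(self, features: np.ndarray) -> np.ndarray:
        _, utilities, _ = assess_batch(features, self.brb, renormalize=self.renormalize)
        return utilities


class SklearnGradeAdapter:
    """Thin adapter fitting an off-the-shelf classifier on grade labels.

    The estimator's internals are deliberately untouched; hyperparameters
    live in the factory functions below and are recorded there because the
    original comparison published none.
    """

    def __init__(self, estimator):
        self.estimator = estimator
        self._fitted = False

    def fit(self, data: LabelledDataset) -> "SklearnGradeAdapter":
        if not data.is_labelled:
            raise ValueError("baseline training requires a labelled dataset")
        self.estimator.fit(data.features, data.grades)
        self._fitted = True
        return self

    def predict_grades(self, features: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("adapter not fitted; call fit(train_data) first")
        return np.asarray(self.estimator.predict(features), dtype=int)


def neural_network_baseline(seed: int = 0) -> SklearnGradeAdapter:
    """Feed-forward (back-propagation) network baseline: one 16-unit hidden layer."""
    from sklearn.neural_network import MLPClassifier

    return SklearnGradeAdapter(
        MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000, random_state=seed)
    )


def svm_baseline(seed: int = 0) -> SklearnGradeAdapter:
    """Support-vector classifier baseline with an RBF kernel."""
    from sklearn.svm import SVC

    return SklearnGradeAdapter(SVC(kernel="rbf", C=1.0, random_state=seed))


@dataclass(frozen=True)
class majority_class_baseline:
    """Predicts one constant grade; the floor any real assessor must beat."""

    grade: int = 1

    def predict_grades(self, features: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(features).shape[0], self.grade, dtype=int)


def evaluate_predictions(
    predicted: np.ndarray,
    data: LabelledDataset,
    grade_utilities: np.ndarray,
    *,
    utilities: np.ndarray | None = None,
) -> EvaluationReport:
    """Score 1-based grade predictions (and optionally continuous utilities).

    The MSE is computed on utilities when given, else on the utilities of
    the predicted grades — so discrete baselines are scored on the same
    scale as the continuous model output.
    """
    if not data.is_labelled:
        raise ValueError("evaluation requires a labelled dataset")
    if len(data) == 0:
        raise ValueError("dataset is empty")
    predicted = np.asarray(predicted, dtype=int)
    N = len(grade_utilities)
    if np.any(predicted < 1) or np.any(predicted > N):
        raise ValueError(f"predicted grades outside 1..{N}")
    true = data.grades
    confusion = np.zeros((N, N), dtype=int)
    np.add.at(confusion, (true - 1, predicted - 1), 1)
    y_r = np.asarray(grade_utilities)[true - 1]
    y_hat = np.asarray(grade_utilities)[predicted - 1] if utilities is None else utilities
    return EvaluationReport(
        accuracy=float(np.trace(confusion) / len(data)),
        mse=float(np.mean((y_hat - y_r) ** 2)),
        confusion=confusion,
        n_records=len(data),
    )


def evaluate(model: BeliefRuleBase, data: LabelledDataset, *, renormalize: bool = False) -> EvaluationReport:
    """Score a rule base: grade accuracy and utility MSE on labelled data."""
    _, utilities, grades = assess_batch(data.features, model, renormalize=renormalize)
    return evaluate_predictions(grades, data, model.grade_utilities, utilities=utilities)


def compare(
    models: dict[str, GradePredictor],
    data: LabelledDataset,
    grade_utilities,
) -> dict[str, EvaluationReport]:
    """Score several named assessors on identical data."""
    if not models:
        raise ValueError("need at least one assessor to compare")
    gu = np.asarray(grade_utilities, dtype=float)
    reports = {}
    for name, model in models.items():
        predicted = model.predict_grades(data.features)
        utilities = None
        if hasattr(model, "predict_utilities"):
            utilities = model.predict_utilities(data.features)
        reports[name] = evaluate_predictions(predicted, data, gu, utilities=utilities)
    return reports


def comparison_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """One row per assessor: accuracy, MSE, record count."""
    return pd.DataFrame(
        {
            "model": list(reports),
            "accuracy": [r.accuracy for r in reports.values()],
            "mse": [r.mse for r in reports.values()],
            "n_records": [r.n_records for r in reports.values()],
        }
    ).set_index("model")
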