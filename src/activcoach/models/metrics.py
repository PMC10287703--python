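"""Evaluation metrics for the classifier and the forecaster.

Classification metrics are computed from the confusion matrix; multi-class
precision/recall use the weighted average over classes, the F1 score is the
harmonic mean of precision and recall, and MCC is the (multi-class) Matthews
correlation coefficient, which is symmetric in the choice of positive class.

Forecast metrics: RMSE; forecast bias FB = mean(expected − predicted), whose
sign convention makes overprediction negative and underprediction positive;
and RSD, the standard deviation of the error series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             matthews_corrcoef, precision_score, recall_score)

from ..errors import ArityError


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    mcc: float
    confusion: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "accuracy": self.accuracy, "f1": self.f1, "mcc": self.mcc}


@dataclass(frozen=True)
class ForecastMetrics:
    rmse: float
    fb: float
    rsd: float

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "fb": self.fb, "rsd": self.rsd}


def evaluate_classification(y_true, y_pred) -> ClassificationMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ArityError("true and predicted labels must be equal-length, non-empty")
    precision = float(precision_score(y_true, y_pred, average="weighted",
                                      zero_division=0))
    recall = float(recall_score(y_true, y_pred, average="weighted",
                                zero_division=0))
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return ClassificationMetrics(
        precision=precision, recall=recall,
        accuracy=float(accuracy_score(y_true, y_pred)), f1=f1,
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred))


def evaluate_forecast(predicted, expected) -> ForecastMetrics:
    predicted = np.asarray(predicted, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if predicted.size == 0 or predicted.shape != expected.shape:
        raise ArityError("predicted and expected must be equal-length, non-empty")
    errors = expected - predicted
    rmse = float(np.sqrt(np.mean((predicted - expected) ** 2)))
    rsd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return ForecastMetrics(rmse=rmse, fb=float(np.mean(errors)), rsd=rsd)


def naive_last_value_rmse(series, test_size: int) -> float:
    """RMSE of the naive forecast (tomorrow = today) on the series tail.

    The baseline every learned forecaster should beat.
    """
    y = np.asarray(series, dtype=float)
    if test_size < 1 or test_size >= y.size:
        raise ArityError("test_size must lie in [1, len(series))")
    pred = y[-test_size - 1:-1]
    actual = y[-test_size:]
    return float(np.sqrt(np.mean((pred - actual) ** 2)))
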