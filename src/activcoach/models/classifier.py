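"""Learned daily activity-level classifier.

A fully connected feed-forward network over the five daily features
(steps, sedentary, LPA, MPA, VPA) with five ReLU hidden layers of widths
32-32-16-16-16 and a softmax output over the five activity levels, trained
with categorical cross-entropy and Adam (α=0.001, β1=0.9, β2=0.999, ε=1e-8,
no decay) and a 5% validation split.  Features are min-max scaled to [0, 1]
before training.  This is the learned counterpart to the deterministic rule
classifier in :mod:`activcoach.levels`, which also provides its training
labels in the synthetic benchmark.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from ..errors import DomainError, InsufficientDataError

#: order of the daily feature columns expected by the classifier
FEATURE_NAMES = ("steps", "sedentary_s", "lpa_s", "mpa_s", "vpa_s")


class ActivityLevelClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator for daily activity-level classification."""

    def __init__(self, hidden_layer_sizes: tuple[int, ...] = (32, 32, 16, 16, 16),
                 epochs: int = 200, batch_size: int | str = "auto",
                 learning_rate: float = 0.001,
                 validation_fraction: float = 0.05,
                 random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y) -> "ActivityLevelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise DomainError("X must be a 2-D feature matrix")
        if not np.all(np.isfinite(X)):
            raise DomainError("features contain NaN or infinite values")
        if np.unique(y).size < 2:
            raise InsufficientDataError(
                "training labels contain a single class")
        self.scaler_ = MinMaxScaler().fit(X)
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu", solver="adam",
            learning_rate_init=self.learning_rate,
            beta_1=0.9, beta_2=0.999, epsilon=1e-8,
            batch_size=self.batch_size, max_iter=self.epochs,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.epochs,  # train the full budget
            random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.mlp_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict(self.scaler_.transform(np.asarray(X, float)))

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities (softmax output), rows summing to 1."""
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict_proba(
            self.scaler_.transform(np.asarray(X, float)))


def daily_feature_matrix(records) -> np.ndarray:
    """Stack daily records into the (steps, sedentary, LPA, MPA, VPA) matrix."""
    return np.asarray([[r.steps, r.sedentary_s, r.lpa_s, r.mpa_s, r.vpa_s]
                       for r in records], dtype=float)
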