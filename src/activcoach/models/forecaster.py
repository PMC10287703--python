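"""Univariate daily-step forecaster: a small 1-D convolutional network.

Architecture (matching the compact design that works well on short wearable
step series): two stride-1 Conv1D layers (kernel size 3, ReLU), one MaxPool1D
layer, a flatten, and a single-unit dense output.  The series is min-max
scaled to [0, 1] before windowing; supervised samples are sliding windows of
``n_steps`` past days predicting the next day.  Training uses MSE loss, Adam
at the standard configuration, a held-out validation tail (fraction 0.05) and
plateau-based learning-rate reduction.  Multi-step forecasts are recursive:
each prediction is appended to the window for the next step, and outputs are
inverse-scaled and clamped at zero steps.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ..errors import DomainError, InsufficientDataError
from ._nn import Adam, Conv1D, Dense, Flatten, MaxPool1D, Sequential, mse


def sliding_windows(series: np.ndarray,
                    n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a 1-D series into (X, y) one-step supervised samples."""
    if series.size <= n_steps + 1:
        raise InsufficientDataError(
            f"series of length {series.size} too short for n_steps={n_steps}")
    X = np.lib.stride_tricks.sliding_window_view(series, n_steps)[:-1]
    y = series[n_steps:]
    return X.copy(), y.copy()


class _MinMax:
    """Min-max scaler to [0, 1] that tolerates a constant series."""

    def fit(self, x: np.ndarray) -> "_MinMax":
        self.lo = float(np.min(x))
        self.hi = float(np.max(x))
        self.span = self.hi - self.lo
        return self

    def transform(self, x):
        if self.span == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return (np.asarray(x, dtype=float) - self.lo) / self.span

    def inverse(self, x):
        return np.asarray(x, dtype=float) * self.span + self.lo


class CNNStepForecaster(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for univariate step-count forecasting.

    Parameters
    ----------
    n_steps : length of the input window, days (one week by default).
    filters : filter counts of the two convolution layers.
    kernel_size : convolution kernel width.
    pool_size : max-pooling width.
    epochs, batch_size : training schedule.
    learning_rate : initial Adam learning rate.
    validation_fraction : tail share of windows held out for the LR plateau
        monitor.
    lr_factor, lr_patience, min_lr : plateau reduction — multiply the
        learning rate by ``lr_factor`` after ``lr_patience`` epochs without
        validation improvement, never below ``min_lr``.
    random_state : seed; fixed seeds give identical fits and forecasts.
    """

    def __init__(self, n_steps: int = 7, filters: tuple[int, int] = (64, 32),
                 kernel_size: int = 3, pool_size: int = 2, epochs: int = 200,
                 batch_size: int = 50, learning_rate: float = 0.001,
                 validation_fraction: float = 0.05, lr_factor: float = 0.5,
                 lr_patience: int = 20, min_lr: float = 1e-5,
                 random_state: int | None = None):
        self.n_steps = n_steps
        self.filters = filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.min_lr = min_lr
        self.random_state = random_state

    def _build(self, rng: np.random.Generator) -> Sequential:
        f1, f2 = self.filters
        conv_out = self.n_steps - 2 * (self.kernel_size - 1)
        if conv_out < 1:
            raise DomainError("n_steps too small for two convolution layers")
        pooled = max(conv_out // self.pool_size, 1)
        pool = MaxPool1D(self.pool_size if conv_out >= self.pool_size else 1)
        return Sequential([
            Conv1D(1, f1, self.kernel_size, rng),
            Conv1D(f1, f2, self.kernel_size, rng),
            pool,
            Flatten(),
            Dense(pooled * f2, 1, rng),
        ])

    def fit(self, series, y=None) -> "CNNStepForecaster":
        """Fit on a 1-D daily step series (length must exceed n_steps + 1)."""
        if self.n_steps < 1:
            raise DomainError("n_steps must be >= 1")
        series = np.asarray(series, dtype=float).ravel()
        if not np.all(np.isfinite(series)):
            raise DomainError("series contains non-finite values")
        rng = np.random.default_rng(self.random_state)
        self.scaler_ = _MinMax().fit(series)
        scaled = self.scaler_.transform(series)
        X, y_t = sliding_windows(scaled, self.n_steps)

        n_val = max(int(round(len(X) * self.validation_fraction)), 1) \
            if self.validation_fraction > 0 and len(X) > 2 else 0
        X_tr, y_tr = X[:len(X) - n_val], y_t[:len(X) - n_val]
        X_val, y_val = X[len(X) - n_val:], y_t[len(X) - n_val:]

        net = self._build(rng)
        opt = Adam(net.params, lr=self.learning_rate)
        best_val = np.inf
        stall = 0
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(len(X_tr))
            epoch_loss = 0.0
            for start in range(0, len(X_tr), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X_tr[idx][:, :, None]
                pred = net.forward(xb)
                loss, grad = mse(pred, y_tr[idx][:, None])
                opt.step(net.backward(grad))
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / max(len(X_tr), 1))
            if n_val:
                val_loss, _ = mse(net.forward(X_val[:, :, None]),
                                  y_val[:, None])
                if val_loss < best_val - 1e-12:
                    best_val, stall = val_loss, 0
                else:
                    stall += 1
                    if stall >= self.lr_patience:
                        opt.lr = max(opt.lr * self.lr_factor, self.min_lr)
                        stall = 0
        self.net_ = net
        self.train_series_ = series
        self.n_features_in_ = self.n_steps
        return self

    def predict(self, X) -> np.ndarray:
        """One-step forecasts for windows of ``n_steps`` raw step counts."""
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        scaled = self.scaler_.transform(X)
        out = self.net_.forward(scaled[:, :, None]).ravel()
        return np.maximum(self.scaler_.inverse(out), 0.0)

    def forecast(self, horizon: int = 7, series=None) -> np.ndarray:
        """Recursive multi-step forecast on the original step scale.

        Each prediction is appended to the input window for the next step.
        ``series`` defaults to the training series; it must hold at least
        ``n_steps`` values.
        """
        check_is_fitted(self, "net_")
        if horizon < 1:
            raise DomainError("horizon must be >= 1")
        hist = (self.train_series_ if series is None
                else np.asarray(series, dtype=float).ravel())
        if hist.size < self.n_steps:
            raise InsufficientDataError(
                f"need at least n_steps={self.n_steps} values to forecast")
        window = list(self.scaler_.transform(hist[-self.n_steps:]))
        out = []
        for _ in range(horizon):
            x = np.asarray(window[-self.n_steps:], dtype=float)[None, :, None]
            pred = float(self.net_.forward(x).ravel()[0])
            window.append(pred)
            out.append(pred)
        return np.maximum(self.scaler_.inverse(np.asarray(out)), 0.0)
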