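"""Feedforward neural network for descriptor-based property prediction.

Architecture: 10 inputs -> 32 ReLU -> 32 ReLU -> 1 linear output, trained
by full-batch gradient descent on the mean squared error with Adam updates
and analytic backpropagation.  Inputs and target are z-scored by default
(descriptor scales span orders of magnitude); predictions are mapped back
to the original scale.

Training is fully deterministic given the seed: initialization is a scaled
uniform draw from a seeded generator and there is no minibatching.  The
returned weights are the ones with the best observed training loss.

With 17 samples and no held-out split, reported metrics are **in-sample**:
they measure capacity to fit, not generalization.

The statsmodels-style surface is :class:`DescriptorANN` (model, built from
data) and :class:`ANNResults` (fit artefacts, metrics panel, ``summary()``);
:func:`train`, :func:`forward` and :func:`regression_metrics` are the
functional layer underneath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ANNConfig", "ANNModel", "MetricsPanel", "DescriptorANN",
           "ANNResults", "train", "forward", "regression_metrics"]

Params = dict[str, np.ndarray]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ANNConfig:
    hidden_sizes: tuple[int, int] = (32, 32)
    learning_rate: float = 1e-3
    max_epochs: int = 20_000
    seed: int = 0
    standardize_inputs: bool = True
    standardize_target: bool = True
    # early stop: quit when the running-best loss improves by less than
    # `tol` over the last `patience` epochs
    tol: float = 1e-10
    patience: int = 500

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("learning_rate must be > 0 and max_epochs >= 1")
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be two positive integers")


@dataclass(frozen=True)
class ANNModel:
    """Trained network: weights/biases plus standardization parameters."""

    params: Params
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    config: ANNConfig
    loss_history: np.ndarray = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.params["W1"].shape[0]


@dataclass(frozen=True)
class MetricsPanel:
    """MSE/MAE/RMSE/R^2 of a prediction against actual values."""

    MSE: float
    MAE: float
    RMSE: float
    R_squared: float

    def as_dict(self) -> dict[str, float]:
        return {"MSE": self.MSE, "MAE": self.MAE, "RMSE": self.RMSE,
                "R2": self.R_squared}


def _init_params(n_in: int, hidden: tuple[int, int],
                 rng: np.random.Generator) -> Params:
    """Scaled uniform init, U(-sqrt(6/fan_in), sqrt(6/fan_in)); zero biases."""
    sizes = [n_in, hidden[0], hidden[1], 1]
    params: Params = {}
    for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:]), start=1):
        lim = math.sqrt(6.0 / fi)
        params[f"W{i}"] = rng.uniform(-lim, lim, size=(fi, fo))
        params[f"b{i}"] = np.zeros(fo)
    return params


def _forward_raw(params: Params, Z: np.ndarray) -> np.ndarray:
    """Network output on already-standardized inputs, standardized scale."""
    h1 = np.maximum(Z @ params["W1"] + params["b1"], 0.0)
    h2 = np.maximum(h1 @ params["W2"] + params["b2"], 0.0)
    return (h2 @ params["W3"] + params["b3"])[:, 0]


def loss_and_grads(params: Params, Z: np.ndarray,
                   t: np.ndarray) -> tuple[float, Params]:
    """MSE loss and its analytic gradients (reverse-mode, by hand).

    ``Z``: standardized inputs (n x d); ``t``: standardized targets (n,).
    Exposed so the backprop arithmetic can be checked against finite
    differences independently of the training loop.
    """
    n = len(t)
    a1 = Z @ params["W1"] + params["b1"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ params["W2"] + params["b2"]
    h2 = np.maximum(a2, 0.0)
    out = (h2 @ params["W3"] + params["b3"])[:, 0]
    err = out - t
    loss = float(err @ err) / n

    d_out = (2.0 / n) * err[:, None]              # dL/d(out), n x 1
    grads: Params = {
        "W3": h2.T @ d_out,
        "b3": d_out.sum(axis=0),
    }
    d_h2 = (d_out @ params["W3"].T) * (a2 > 0.0)
    grads["W2"] = h1.T @ d_h2
    grads["b2"] = d_h2.sum(axis=0)
    d_h1 = (d_h2 @ params["W2"].T) * (a1 > 0.0)
    grads["W1"] = Z.T @ d_h1
    grads["b1"] = d_h1.sum(axis=0)
    return loss, grads


def train(X, y, config: ANNConfig = ANNConfig()) -> ANNModel:
    """Fit the network to ``(X, y)`` by full-batch Adam on the MSE.

    Returns the model at the best observed training loss.  Raises
    :class:`DivergenceError` on non-finite loss (lower the learning rate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or len(X) != len(y):
        raise ValueError("X must be n x d and y length n")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing/non-finite values are not supported")

    if config.standardize_inputs:
        x_mean, x_std = X.mean(axis=0), X.std(axis=0)
        x_std = np.where(x_std > 0, x_std, 1.0)
    else:
        x_mean, x_std = np.zeros(X.shape[1]), np.ones(X.shape[1])
    if config.standardize_target:
        y_mean, y_std = float(y.mean()), float(y.std())
        y_std = y_std if y_std > 0 else 1.0
    else:
        y_mean, y_std = 0.0, 1.0
    Z = (X - x_mean) / x_std
    t = (y - y_mean) / y_std

    rng = np.random.default_rng(config.seed)
    params = _init_params(X.shape[1], config.hidden_sizes, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_loss = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_at = 0
    history = np.empty(config.max_epochs)
    n_done = 0
    for epoch in range(1, config.max_epochs + 1):
        loss, grads = loss_and_grads(params, Z, t)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training diverged (non-finite loss); lower learning_rate")
        history[n_done] = loss
        n_done += 1
        if loss < best_loss - config.tol:
            best_loss, best_at = loss, epoch
            best_params = {k: p.copy() for k, p in params.items()}
        elif loss < best_loss:
            best_loss = loss
            best_params = {k: p.copy() for k, p in params.items()}
        if epoch - best_at >= config.patience:
            break
        bc1 = 1.0 - beta1 ** epoch
        bc2 = 1.0 - beta2 ** epoch
        for k in params:
            g = grads[k]
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            params[k] = params[k] - config.learning_rate * (
                (m[k] / bc1) / (np.sqrt(v[k] / bc2) + eps))

    return ANNModel(params=best_params, x_mean=x_mean, x_std=x_std,
                    y_mean=y_mean, y_std=y_std, config=config,
                    loss_history=history[:n_done])


def forward(model: ANNModel, X) -> np.ndarray:
    """Deterministic predictions on the original target scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, "
                         f"got {X.shape[1]}")
    Z = (X - model.x_mean) / model.x_std
    return _forward_raw(model.params, Z) * model.y_std + model.y_mean


def regression_metrics(y_actual, y_pred) -> MetricsPanel:
    """MSE, MAE, RMSE and R^2 = 1 - RSS/TSS of predictions vs actuals."""
    y_actual = np.asarray(y_actual, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_actual.shape != y_pred.shape or y_actual.ndim != 1:
        raise ValueError("y_actual and y_pred must be 1-d of equal length")
    if len(y_actual) < 2:
        raise ValueError("need at least 2 points")
    resid = y_actual - y_pred
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))
    tss = float(np.sum((y_actual - y_actual.mean()) ** 2))
    if tss <= 0.0:
        raise ValueError("constant y_actual: R^2 undefined")
    r2 = 1.0 - float(resid @ resid) / tss
    return MetricsPanel(MSE=mse, MAE=mae, RMSE=math.sqrt(mse), R_squared=r2)


class DescriptorANN:
    """Model object: network regression of one property on the descriptors.

    Parameters
    ----------
    y : array-like, length n
        Property values.
    X : array-like or DataFrame, n x d
        Descriptor matrix; column names are kept for attribution reports.
    config : ANNConfig
    """

    def __init__(self, y, X, config: ANNConfig = ANNConfig()):
        import pandas as pd
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.config = config

    def fit(self, seed: int | None = None) -> "ANNResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        model = train(self.X, self.y, cfg)
        pred = forward(model, self.X)
        return ANNResults(model=model, parent=self, fittedvalues=pred,
                          metrics=regression_metrics(self.y, pred))


@dataclass(frozen=True)
class ANNResults:
    model: ANNModel
    parent: DescriptorANN
    fittedvalues: np.ndarray
    metrics: MetricsPanel

    def predict(self, X) -> np.ndarray:
        return forward(self.model, X)

    def summary(self) -> str:
        m, c = self.metrics, self.model.config
        return "\n".join([
            f"Descriptor ANN ({self.model.n_features} -> "
            f"{c.hidden_sizes[0]} -> {c.hidden_sizes[1]} -> 1, ReLU)",
            f"  n = {len(self.parent.y)}, seed = {c.seed}, "
            f"epochs run = {len(self.model.loss_history)}",
            f"  in-sample: MSE = {m.MSE:.4f}  MAE = {m.MAE:.4f}  "
            f"RMSE = {m.RMSE:.4f}  R^2 = {m.R_squared:.4f}",
        ])

    def weights_dict(self) -> dict:
        """JSON-serializable weights + standardization parameters."""
        return {
            "params": {k: v.tolist() for k, v in self.model.params.items()},
            "x_mean": self.model.x_mean.tolist(),
            "x_std": self.model.x_std.tolist(),
            "y_mean": self.model.y_mean,
            "y_std": self.model.y_std,
            "features": self.parent.feature_names,
        }
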