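"""Point, error-network and distributional LOS predictors.

Three seed-deterministic fits built on the dense-network engine:

* :func:`train_regressor` — a feed-forward network minimizing mean squared
  error; its training-set RMSE is the global error scale of the "RMSE
  method" (intervals LOS_pred +/- alpha * RMSE, identical width for every
  patient).
* :func:`train_error_net` — a second network mapping features to each
  patient's own error magnitude |LOS - LOS_pred| (the "ERR_pred method");
  a softplus output transform keeps the predicted half-width non-negative.
  A signed mode (target LOS - LOS_pred) is available behind a flag.
* :func:`train_dist_net` — a two-output network predicting (mu_pred, z)
  with sigma_pred = e^z, trained with one of the custom interval losses
  from :mod:`losrange.losses`.

Features are standardized per numeric column and one-hot encoded per
categorical column; targets are standardized by default and inverse
transformed before reporting, so optimization behaves the same across
regimes whose LOS scales differ by an order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, clip_grad_norm, sigmoid, softplus
from .cohort import CohortTable
from .errors import (
    ConfigurationError,
    EmptyCohortError,
    FeatureMismatchError,
    TrainingDivergenceError,
)
from .losses import LossConfig, loss1_value_grad, loss2_value_grad, loss3_value_grad

__all__ = [
    "NetConfig",
    "DistPrediction",
    "RegressorFit",
    "ErrorNetFit",
    "DistNetFit",
    "train_regressor",
    "predict_los",
    "train_error_net",
    "predict_error",
    "train_dist_net",
    "predict_dist",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimization settings shared by all network fits.

    ``grad_clip_norm="auto"`` resolves to 1.0 for loss1/loss2 (whose flat
    or kinked surfaces destabilize training) and to no clipping otherwise.
    """

    hidden_sizes: tuple = (64, 64, 64)
    activation: str = "relu"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    early_stop_patience: int = 10
    grad_clip_norm: Union[float, str, None] = "auto"
    weight_decay: float = 1e-3
    seed: int = 0
    target_standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("learning_rate, batch_size, max_epochs must be positive")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be positive")
        if self.activation != "relu":
            raise ConfigurationError("only the rectifier activation is supported")

    def resolve_clip(self, loss_id: Optional[str]) -> Optional[float]:
        if self.grad_clip_norm == "auto":
            return 1.0 if loss_id in ("loss1", "loss2") else None
        return self.grad_clip_norm


@dataclass
class DistPrediction:
    """Per-sample normal parameters (hours); sigma = e^z > 0 by construction."""

    mu: np.ndarray
    sigma: np.ndarray


# ---------------------------------------------------------------------------
# feature preprocessing
# ---------------------------------------------------------------------------

class DesignMatrix:
    """Column-wise standardizer / one-hot encoder with schema checking."""

    def __init__(self) -> None:
        self.numeric_cols: list[str] = []
        self.cat_cols: list[str] = []
        self.means: np.ndarray | None = None
        self.stds: np.ndarray | None = None
        self.categories: dict[str, list] = {}

    def fit(self, df: pd.DataFrame) -> "DesignMatrix":
        self.numeric_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        self.cat_cols = [c for c in df.columns if c not in self.numeric_cols]
        num = df[self.numeric_cols].to_numpy(dtype=float)
        self.means = num.mean(axis=0) if num.size else np.zeros(0)
        stds = num.std(axis=0) if num.size else np.zeros(0)
        self.stds = np.where(stds > 0, stds, 1.0)
        self.categories = {
            c: sorted(df[c].astype(str).unique().tolist()) for c in self.cat_cols
        }
        return self

    @property
    def width(self) -> int:
        return len(self.numeric_cols) + sum(len(v) for v in self.categories.values())

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        expected = set(self.numeric_cols) | set(self.cat_cols)
        got = set(df.columns)
        if expected != got:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise FeatureMismatchError(
                f"schema mismatch; missing columns {missing}, unexpected columns {extra}"
            )
        parts = []
        if self.numeric_cols:
            num = df[self.numeric_cols].to_numpy(dtype=float)
            parts.append((num - self.means) / self.stds)
        for c in self.cat_cols:
            levels = self.categories[c]
            vals = df[c].astype(str).to_numpy()
            onehot = (vals[:, None] == np.array(levels)[None, :]).astype(float)
            parts.append(onehot)
        return np.concatenate(parts, axis=1) if parts else np.zeros((len(df), 0))


class TargetScaler:
    """z-scoring of the regression target, invertible for reporting."""

    def __init__(self, y: np.ndarray, enabled: bool) -> None:
        self.enabled = enabled
        self.mean = float(np.mean(y)) if enabled else 0.0
        sd = float(np.std(y)) if enabled else 1.0
        self.scale = sd if sd > 0 else 1.0

    def encode(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.scale

    def decode(self, y_std: np.ndarray) -> np.ndarray:
        return y_std * self.scale + self.mean


# ---------------------------------------------------------------------------
# generic minibatch training loop
# ---------------------------------------------------------------------------

def _train_loop(
    net: MLP,
    X: np.ndarray,
    T: np.ndarray,
    loss_grad: Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]],
    config: NetConfig,
    rng: np.random.Generator,
    clip: Optional[float],
) -> tuple[list, bool]:
    """Minibatch Adam with early stopping on a 10% validation slice.

    ``loss_grad(out, t)`` returns (mean batch loss, d loss / d out).
    L2 weight decay applies to weight matrices only; the learning rate is
    halved when the validation loss stagnates for a third of the patience
    window (up to three times) before early stopping restores the best
    parameters.  Returns (history, converged) where ``converged`` is False
    when the fit exhausted ``max_epochs`` without the validation loss
    plateauing.
    """
    n = len(X)
    n_val = int(0.1 * n) if n >= 20 else 0
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, Ttr = X[tr_idx], T[tr_idx]
    Xval, Tval = X[val_idx], T[val_idx]

    opt = Adam(net.params, lr=config.learning_rate)
    n_weights = len(net.W)
    decay_at = {max(config.early_stop_patience // 3, 1) * k for k in (1, 2, 3)}
    best_val = math.inf
    best_params = net.copy_params()
    patience = 0
    history: list[dict] = []
    converged = False
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(Xtr))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(Xtr), config.batch_size):
            idx = perm[start : start + config.batch_size]
            out, cache = net.forward(Xtr[idx], want_cache=True)
            loss, dout = loss_grad(out, Ttr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite training loss at epoch {epoch}")
            dW, db, _ = net.backward(cache, dout)
            grads = dW + db
            if config.weight_decay:
                for g, p in zip(grads[:n_weights], net.W):
                    g += config.weight_decay * p
            if clip is not None:
                clip_grad_norm(grads, clip)
            opt.step(net.params, grads)
            ep_loss += loss
            n_batches += 1
        train_loss = ep_loss / max(n_batches, 1)
        if n_val:
            val_loss = float(loss_grad(net.forward(Xval), Tval)[0])
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = net.copy_params()
            patience = 0
        else:
            patience += 1
            if patience in decay_at:
                opt.lr *= 0.5
            if patience >= config.early_stop_patience:
                converged = True
                break
    net.set_params(best_params)
    return history, converged


def _check_table(table: CohortTable) -> None:
    if len(table) == 0:
        raise EmptyCohortError("training table is empty")
    if table.features.isna().any().any():
        raise ConfigurationError("training table has missing values; impute first")


# ---------------------------------------------------------------------------
# point regressor (RMSE method)
# ---------------------------------------------------------------------------

@dataclass
class RegressorFit:
    net: MLP
    dm: DesignMatrix
    scaler: TargetScaler
    rmse_train: float
    rmse_test: Optional[float]
    history: list = field(default_factory=list, repr=False)
    converged: bool = True
    config: NetConfig = NetConfig()


def train_regressor(
    train: CohortTable, config: NetConfig = NetConfig(), test: Optional[CohortTable] = None
) -> RegressorFit:
    """Fit the mean-squared-error point predictor and record its RMSE."""
    _check_table(train)
    rng = np.random.default_rng(config.seed)
    dm = DesignMatrix().fit(train.features)
    X = dm.transform(train.features)
    scaler = TargetScaler(train.los_hours, config.target_standardize)
    T = scaler.encode(train.los_hours)[:, None]

    net = MLP(dm.width, config.hidden_sizes, 1, rng)

    def mse_grad(out, t):
        r = out - t
        return float(np.mean(r * r)), 2.0 * r / len(r)

    history, converged = _train_loop(
        net, X, T, mse_grad, config, rng, config.resolve_clip(None)
    )
    fit = RegressorFit(net, dm, scaler, 0.0, None, history, converged, config)
    pred = predict_los(fit, train)
    fit.rmse_train = float(np.sqrt(np.mean((pred - train.los_hours) ** 2)))
    if test is not None and len(test):
        pt = predict_los(fit, test)
        fit.rmse_test = float(np.sqrt(np.mean((pt - test.los_hours) ** 2)))
    return fit


def predict_los(fit: RegressorFit, table: CohortTable) -> np.ndarray:
    """Point LOS prediction in hours, one value per row."""
    if len(table) == 0:
        return np.zeros(0)
    X = fit.dm.transform(table.features)
    return fit.scaler.decode(fit.net.forward(X)[:, 0])


# ---------------------------------------------------------------------------
# error network (ERR_pred method)
# ---------------------------------------------------------------------------

@dataclass
class ErrorNetFit:
    net: MLP
    dm: DesignMatrix
    scale: float
    signed: bool
    base: RegressorFit
    history: list = field(default_factory=list, repr=False)
    converged: bool = True


def train_error_net(
    train: CohortTable,
    base: RegressorFit,
    config: NetConfig = NetConfig(),
    signed: bool = False,
) -> ErrorNetFit:
    """Fit a second network predicting each patient's own error magnitude.

    Default target is |LOS - LOS_pred| with a softplus output so the
    predicted half-width is non-negative; ``signed=True`` instead regresses
    the raw residual LOS - LOS_pred with a linear output.
    """
    _check_table(train)
    rng = np.random.default_rng(config.seed + 1)
    resid = train.los_hours - predict_los(base, train)
    target = resid if signed else np.abs(resid)
    scale = float(np.std(target))
    scale = scale if scale > 0 else 1.0
    T = (target / scale)[:, None]
    X = base.dm.transform(train.features)
    net = MLP(base.dm.width, config.hidden_sizes, 1, rng)

    if signed:

        def grad(out, t):
            r = out - t
            return float(np.mean(r * r)), 2.0 * r / len(r)

    else:

        def grad(out, t):
            p = softplus(out)
            r = p - t
            return float(np.mean(r * r)), 2.0 * r * sigmoid(out) / len(r)

    history, converged = _train_loop(net, X, T, grad, config, rng, config.resolve_clip(None))
    return ErrorNetFit(net, base.dm, scale, signed, base, history, converged)


def predict_error(fit: ErrorNetFit, table: CohortTable) -> np.ndarray:
    """Predicted per-patient error magnitude ERR_pred(x) >= 0, in hours."""
    if len(table) == 0:
        return np.zeros(0)
    out = fit.net.forward(fit.dm.transform(table.features))[:, 0]
    if fit.signed:
        return out * fit.scale
    return softplus(out) * fit.scale


# ---------------------------------------------------------------------------
# distributional network (Dis_pred methods)
# ---------------------------------------------------------------------------

@dataclass
class DistNetFit:
    net: MLP
    dm: DesignMatrix
    scaler: TargetScaler
    loss_config: LossConfig
    history: list = field(default_factory=list, repr=False)
    converged: bool = True


def train_dist_net(
    train: CohortTable,
    loss_config: LossConfig = LossConfig(),
    config: NetConfig = NetConfig(),
) -> DistNetFit:
    """Fit the two-output (mu_pred, z) network with a custom interval loss.

    The loss operates in the standardized target space; sigma_0 (hours) is
    rescaled accordingly.  A fit that exhausts ``max_epochs`` without the
    validation loss plateauing is returned with ``converged=False`` — loss1
    in particular is prone to this.
    """
    _check_table(train)
    rng = np.random.default_rng(config.seed + 2)
    dm = DesignMatrix().fit(train.features)
    X = dm.transform(train.features)
    scaler = TargetScaler(train.los_hours, config.target_standardize)
    T = scaler.encode(train.los_hours)[:, None]
    sigma0_std = loss_config.resolved_sigma0 / scaler.scale
    lid = loss_config.loss_id

    def grad(out, t):
        mu, z = out[:, 0], out[:, 1]
        mu0 = t[:, 0]
        if lid == "loss1":
            val, dmu, dz = loss1_value_grad(mu, z, mu0, loss_config.loss1_variant)
        elif lid == "loss2":
            val, dmu, dz = loss2_value_grad(
                mu, z, mu0, sigma0_std, loss_config.loss2_variant
            )
        else:
            val, dmu, dz = loss3_value_grad(
                mu, z, mu0, sigma0_std, loss_config.lambda_penalty, loss_config.epsilon
            )
        dout = np.stack([dmu, dz], axis=1) / len(mu)
        return float(np.mean(val)), dout

    net = MLP(dm.width, config.hidden_sizes, 2, rng)
    history, converged = _train_loop(
        net, X, T, grad, config, rng, config.resolve_clip(lid)
    )
    return DistNetFit(net, dm, scaler, loss_config, history, converged)


def predict_dist(fit: DistNetFit, table: CohortTable) -> DistPrediction:
    """Per-patient (mu_pred, sigma_pred) in hours; sigma_pred > 0 always."""
    if len(table) == 0:
        return DistPrediction(np.zeros(0), np.zeros(0))
    out = fit.net.forward(fit.dm.transform(table.features))
    mu = fit.scaler.decode(out[:, 0])
    sigma = np.exp(np.clip(out[:, 1], -30.0, 30.0)) * fit.scaler.scale
    return DistPrediction(mu, sigma)
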