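"""Interval construction, coverage accuracy, overall prediction error.

Every method reduces to the same interval recipe: per patient,
``center +/- alpha * scale`` with the lower bound clamped at zero, where
``scale`` is the method's error quantity — a constant RMSE, a per-patient
predicted error magnitude, a predicted sigma, or a generated-sample SD.
A prediction is *correct* when the observed LOS falls inside the closed
interval; *accuracy* is the fraction of correct predictions, monotone
non-decreasing in alpha.  The *overall prediction error* (OPE) is the mean
unclamped half-width, alpha * mean(scale) — an interval-width budget that
lets methods be compared at matched cost.  ``calibrate_alpha`` finds the
smallest grid alpha reaching a target accuracy (the grid step of 0.01
matches the precision at which alphas are conventionally reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "METHODS",
    "IntervalSet",
    "EvalCurve",
    "CalibrationResult",
    "build_intervals",
    "coverage_accuracy",
    "overall_prediction_error",
    "calibrate_alpha",
    "accuracy_curve",
    "compare_methods",
]

METHODS = ("rmse", "err_pred", "dis_loss1", "dis_loss2", "dis_loss3", "wgan_gp")


@dataclass
class IntervalSet:
    """Per-patient LOS ranges for one method at one alpha."""

    method: str
    alpha: float
    center: np.ndarray
    half_width: np.ndarray
    scale: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return np.maximum(self.center - self.half_width, 0.0)

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.half_width

    def __len__(self) -> int:
        return len(self.center)


@dataclass
class EvalCurve:
    alpha_grid: np.ndarray
    accuracy: np.ndarray
    ope: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alpha_grid, "accuracy": self.accuracy, "ope": self.ope}
        )


@dataclass(frozen=True)
class CalibrationResult:
    alpha_star: float
    achieved_accuracy: float
    ope_at_alpha_star: float


def build_intervals(
    method: str, centers: np.ndarray, scales: np.ndarray, alpha: float
) -> IntervalSet:
    """Intervals center +/- alpha*scale, lower bound clamped at zero.

    The clamp is coverage-neutral because observed LOS is non-negative.
    """
    centers = np.asarray(centers, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if np.isscalar(scales) or scales.ndim == 0:
        scales = np.full_like(centers, float(scales))
    if centers.shape != scales.shape:
        raise ConfigurationError("centers and scales must have equal length")
    if alpha < 0:
        raise ConfigurationError("alpha must be non-negative")
    if np.any(scales < 0):
        raise ConfigurationError("scales must be non-negative")
    return IntervalSet(method, float(alpha), centers, alpha * scales, scales)


def coverage_accuracy(intervals: IntervalSet, los_true: np.ndarray) -> float:
    """Fraction of patients whose true LOS lies in the closed interval."""
    los_true = np.asarray(los_true, dtype=float)
    if los_true.shape != intervals.center.shape:
        raise ConfigurationError("los_true length must match the interval set")
    covered = (los_true >= intervals.lower) & (los_true <= intervals.upper)
    return float(np.mean(covered))


def overall_prediction_error(intervals: IntervalSet) -> float:
    """Mean unclamped half-width: alpha * mean(scale), in hours."""
    return float(np.mean(intervals.half_width))


def _alpha_required(centers, scales, los_true) -> np.ndarray:
    """Smallest alpha covering each row (closed intervals, zero clamp)."""
    centers = np.asarray(centers, dtype=float)
    scales = np.asarray(scales, dtype=float)
    los_true = np.asarray(los_true, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.abs(los_true - centers) / scales
    a[np.isnan(a)] = 0.0  # zero scale, zero residual
    return a


def calibrate_alpha(
    centers: np.ndarray,
    scales: np.ndarray,
    los_true: np.ndarray,
    target_accuracy: float = 0.95,
    grid_step: float = 0.01,
    alpha_max: float = 50.0,
) -> CalibrationResult:
    """Smallest grid alpha whose coverage reaches ``target_accuracy``.

    Coverage is monotone in alpha, so a scan over the grid is exact.
    """
    if not (0.0 < target_accuracy <= 1.0):
        raise ConfigurationError("target_accuracy must lie in (0, 1]")
    if grid_step <= 0:
        raise ConfigurationError("grid_step must be positive")
    a_req = np.sort(_alpha_required(centers, scales, los_true))
    n = len(a_req)
    grid = np.arange(0.0, alpha_max + grid_step / 2, grid_step)
    # coverage at alpha = fraction of a_req <= alpha
    cov = np.searchsorted(a_req, grid * (1 + 1e-12), side="right") / n
    ok = np.flatnonzero(cov >= target_accuracy)
    if ok.size == 0:
        raise CalibrationError(
            f"target accuracy {target_accuracy} unreachable for alpha <= {alpha_max}; "
            f"max achievable {cov[-1]:.4f}"
        )
    k = int(ok[0])
    alpha_star = float(grid[k])
    mean_scale = float(np.mean(scales)) if np.ndim(scales) else float(scales)
    return CalibrationResult(
        alpha_star=alpha_star,
        achieved_accuracy=float(cov[k]),
        ope_at_alpha_star=alpha_star * mean_scale,
    )


def accuracy_curve(
    centers: np.ndarray,
    scales: np.ndarray,
    los_true: np.ndarray,
    alpha_grid: Sequence[float],
) -> EvalCurve:
    """Coverage accuracy and OPE along an increasing alpha grid."""
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ConfigurationError("alpha_grid must be strictly increasing")
    a_req = np.sort(_alpha_required(centers, scales, los_true))
    cov = np.searchsorted(a_req, grid * (1 + 1e-12), side="right") / len(a_req)
    mean_scale = float(np.mean(scales))
    return EvalCurve(alpha_grid=grid, accuracy=cov, ope=grid * mean_scale)


def compare_methods(
    methods: Mapping[str, tuple[np.ndarray, np.ndarray]],
    los_true: np.ndarray,
    error_budgets: Sequence[float] = (48.0, 96.0),
    target_accuracy: float = 0.95,
    grid_step: float = 0.01,
    alpha_max: float = 50.0,
) -> pd.DataFrame:
    """Compare methods by OPE at target accuracy and accuracy at fixed OPE.

    ``methods`` maps method name -> (centers, scales) on a common test set.
    For a fixed budget b the implied alpha is b / mean(scale).  Methods
    whose target accuracy is unreachable get NaN in the OPE columns rather
    than failing the whole comparison.
    """
    rows = []
    for name, (centers, scales) in methods.items():
        scales = np.asarray(scales, dtype=float)
        if scales.ndim == 0:
            scales = np.full(len(np.asarray(centers)), float(scales))
        row: dict = {"method": name, "mean_scale": float(np.mean(scales))}
        try:
            cal = calibrate_alpha(
                centers, scales, los_true, target_accuracy, grid_step, alpha_max
            )
            row["alpha_star"] = cal.alpha_star
            row["ope_at_target"] = cal.ope_at_alpha_star
            row["achieved_accuracy"] = cal.achieved_accuracy
        except CalibrationError:
            row["alpha_star"] = np.nan
            row["ope_at_target"] = np.nan
            row["achieved_accuracy"] = np.nan
        for b in error_budgets:
            alpha_b = b / row["mean_scale"]
            iv = build_intervals(name, centers, scales, alpha_b)
            row[f"accuracy_at_{b:g}"] = coverage_accuracy(iv, los_true)
        rows.append(row)
    return pd.DataFrame(rows)
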