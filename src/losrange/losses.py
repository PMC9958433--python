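"""Distributional training losses for LOS range prediction.

A two-output network predicts, per patient, the parameters (mu_pred, z) of
a normal LOS distribution with sigma_pred = e^z (the log parameterization
guarantees sigma_pred > 0).  The observed LOS plays the role of the target
mean mu_0, with a target spread sigma_0 that is conceptually a point mass
(sigma_0 -> 0) but must be concrete where the formula requires it.

Three losses are provided:

* ``loss1`` — difference between target and predicted probability mass over
  a +/-1-unit window around mu_0, expressed through the Gauss error
  function.  Its surface is nearly flat over most of the (mu, z) plane,
  which makes training unstable (gradient clipping is on by default for it).
* ``loss2`` — one minus the normalized overlap of the intervals
  [mu_0 - sigma_0, mu_0 + sigma_0] and [mu_pred - sigma_pred,
  mu_pred + sigma_pred].  Two normalizers are implemented: the ``printed``
  form divides by 2(mu_0 + mu_pred) and does *not* vanish at matching
  parameters; the default ``overlap`` form divides by sigma_0 + sigma_pred
  and is zero exactly when the intervals coincide.
* ``loss3`` — squared distance between (mu, sigma) pairs (the closed-form
  2-Wasserstein distance between normals) plus a coupling penalty
  lambda * (mu_pred - mu_0)^2 / (sigma_pred^2 + eps) that stops sigma from
  collapsing to zero against a point-mass target.

All functions are vectorized over numpy arrays and return plain values;
the ``*_value_grad`` variants additionally return analytic partial
derivatives with respect to (mu_pred, z) for use as training objectives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .errors import ConfigurationError

__all__ = [
    "LossConfig",
    "erf_eval",
    "loss1",
    "loss2",
    "loss3",
    "loss1_value_grad",
    "loss2_value_grad",
    "loss3_value_grad",
]

Z_CLAMP = 30.0  # |z| bound inside loss1; e^(2*30) is far beyond any useful sigma
_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)

LOSS_IDS = ("loss1", "loss2", "loss3")


@dataclass(frozen=True)
class LossConfig:
    """Selection and hyperparameters of a distributional training loss.

    ``sigma0`` defaults per loss: 1.0 h for loss2 (the overlap needs a
    non-degenerate target interval) and 0.0 h for loss3 (well-defined at a
    point mass).  ``lambda_penalty`` has no published value; 1.0 is the
    package default.
    """

    loss_id: str = "loss3"
    lambda_penalty: float = 1.0
    epsilon: float = 1e-6
    sigma0: Optional[float] = None
    loss2_variant: str = "overlap"  # or "printed"
    loss1_variant: str = "printed"  # or "exp_z"

    def __post_init__(self) -> None:
        if self.loss_id not in LOSS_IDS:
            raise ConfigurationError(f"unknown loss_id {self.loss_id!r}; expected one of {LOSS_IDS}")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.lambda_penalty < 0:
            raise ConfigurationError("lambda_penalty must be non-negative")
        if self.loss2_variant not in ("overlap", "printed"):
            raise ConfigurationError(f"unknown loss2 variant {self.loss2_variant!r}")
        if self.loss1_variant not in ("printed", "exp_z"):
            raise ConfigurationError(f"unknown loss1 variant {self.loss1_variant!r}")
        if self.sigma0 is not None and self.sigma0 < 0:
            raise ConfigurationError("sigma0 must be non-negative")

    @property
    def resolved_sigma0(self) -> float:
        if self.sigma0 is not None:
            return self.sigma0
        return 1.0 if self.loss_id == "loss2" else 0.0


def erf_eval(x):
    """Gauss error function erf(x) = (2/sqrt(pi)) * int_0^x exp(-t^2) dt."""
    return special.erf(x)


# ---------------------------------------------------------------------------
# loss 1: probability-mass difference over mu_0 +/- 1
# ---------------------------------------------------------------------------

def loss1_value_grad(mu_pred, z, mu0, variant: str = "printed"):
    """Loss 1 with analytic d/d(mu_pred) and d/dz.

    value = [e^-z erf(c s (d+1)) - e^-z erf(c s (d-1))] / (2 e^-2z)
          = (e^z / 2) [erf(c s (d+1)) - erf(c s (d-1))]
    with c = 0.707, d = mu_pred - mu0 and s = e^-2z as printed
    (s = e^-z for the ``exp_z`` variant).
    """
    d = np.asarray(mu_pred, dtype=float) - np.asarray(mu0, dtype=float)
    z = np.clip(np.asarray(z, dtype=float), -Z_CLAMP, Z_CLAMP)
    s = np.exp(-2.0 * z) if variant == "printed" else np.exp(-z)
    s_dz = -2.0 if variant == "printed" else -1.0  # d(ln s)/dz
    c = 0.707
    a1 = c * s * (d + 1.0)
    a2 = c * s * (d - 1.0)
    pref = 0.5 * np.exp(z)
    with np.errstate(over="ignore", under="ignore"):
        val = pref * (special.erf(a1) - special.erf(a2))
        e1 = _TWO_OVER_SQRT_PI * np.exp(-np.square(a1))
        e2 = _TWO_OVER_SQRT_PI * np.exp(-np.square(a2))
    d_dd = pref * (e1 - e2) * c * s
    # a_i depends on z through s: da_i/dz = s_dz * a_i
    d_dz = val + pref * (e1 * a1 - e2 * a2) * s_dz
    return val, d_dd, d_dz


def loss1(mu_pred, z, mu0, variant: str = "printed"):
    """Probability-mass difference loss (see module docstring)."""
    return loss1_value_grad(mu_pred, z, mu0, variant)[0]


# ---------------------------------------------------------------------------
# loss 2: interval overlap
# ---------------------------------------------------------------------------

def _overlap(mu0, sigma0, mu, sigma):
    lo = np.maximum(mu0 - sigma0, mu - sigma)
    hi = np.minimum(mu0 + sigma0, mu + sigma)
    return hi - lo  # negative when disjoint; not clamped to keep gradients


def loss2_value_grad(mu_pred, z, mu0, sigma0, variant: str = "overlap"):
    """Interval-overlap loss with analytic gradients wrt (mu_pred, z)."""
    mu = np.asarray(mu_pred, dtype=float)
    z = np.asarray(z, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    sigma0 = np.asarray(sigma0, dtype=float)
    if np.any(sigma0 <= 0):
        raise ConfigurationError("loss2 requires sigma0 > 0")
    sigma = np.exp(np.clip(z, -Z_CLAMP, Z_CLAMP))
    a, b = mu + sigma, mu - sigma  # predicted upper/lower
    a0, b0 = mu0 + sigma0, mu0 - sigma0
    ov = np.minimum(a0, a) - np.maximum(b0, b)
    # partials of ov wrt predicted endpoints (ties broken toward the target)
    d_ov_da = (a < a0).astype(float)
    d_ov_db = -(b > b0).astype(float)
    d_ov_dmu = d_ov_da + d_ov_db
    d_ov_dsigma = d_ov_da - d_ov_db
    if variant == "overlap":
        denom = sigma0 + sigma
        val = 1.0 - ov / denom
        d_dmu = -d_ov_dmu / denom
        d_dsigma = -d_ov_dsigma / denom + ov / denom**2
    elif variant == "printed":
        denom = 2.0 * (mu0 + mu)
        if np.any(denom == 0):
            raise ConfigurationError("printed loss2 undefined at mu0 + mu_pred = 0")
        val = 1.0 - ov / denom
        d_dmu = -d_ov_dmu / denom + 2.0 * ov / denom**2
        d_dsigma = -d_ov_dsigma / denom
    else:
        raise ConfigurationError(f"unknown loss2 variant {variant!r}")
    return val, d_dmu, d_dsigma * sigma  # chain rule: d sigma/dz = sigma


def loss2(mu_pred, z, mu0, sigma0, variant: str = "overlap"):
    """Interval-overlap loss (default normalizer sigma0 + sigma_pred)."""
    return loss2_value_grad(mu_pred, z, mu0, sigma0, variant)[0]


# ---------------------------------------------------------------------------
# loss 3: Wasserstein-style distance with coupling penalty
# ---------------------------------------------------------------------------

def loss3_value_grad(mu_pred, z, mu0, sigma0, lambda_penalty: float = 1.0,
                     epsilon: float = 1e-6):
    """Loss 3 with analytic gradients wrt (mu_pred, z)."""
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    mu = np.asarray(mu_pred, dtype=float)
    z = np.asarray(z, dtype=float)
    d = mu - np.asarray(mu0, dtype=float)
    sigma = np.exp(np.clip(z, -Z_CLAMP, Z_CLAMP))
    ds = sigma - np.asarray(sigma0, dtype=float)
    denom = sigma**2 + epsilon
    val = d**2 + ds**2 + lambda_penalty * d**2 / denom
    d_dmu = 2.0 * d * (1.0 + lambda_penalty / denom)
    d_dsigma = 2.0 * ds - 2.0 * lambda_penalty * d**2 * sigma / denom**2
    return val, d_dmu, d_dsigma * sigma


def loss3(mu_pred, z, mu0, sigma0=0.0, lambda_penalty: float = 1.0,
          epsilon: float = 1e-6):
    """Squared (mu, sigma) distance plus collapse-preventing penalty."""
    return loss3_value_grad(mu_pred, z, mu0, sigma0, lambda_penalty, epsilon)[0]
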