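"""Error-driven learning models of explicit reward prediction.

Three nested model families predict the stated reward expectation on each
trial of a variable-reward task:

* Rescorla-Wagner (RW): a constant learning rate ``alpha`` moves the
  prediction toward each outcome, ``P[t+1] = P[t] + alpha * delta[t]`` with
  ``delta[t] = reward[t] - P[t]``.
* Pearce-Hall (PH): the learning rate is dynamic; it mixes the previous rate
  with the unsigned prediction error normalised to the 100-point scale,
  ``alpha[t+1] = eta * |delta[t]|/100 + (1 - eta) * alpha[t]``. ``eta = 0``
  reduces PH to RW.
* Variance-adaptive PH: the prediction error is additionally divided by a
  scaling factor ``omega[t] = (1 - nu) + nu * f(sigma[t])`` where
  ``sigma[t]`` is the standard deviation of rewards received up to and
  including trial ``t`` and ``f`` is the identity (linear scaling) or the
  natural logarithm (log scaling). ``nu = 0`` reduces the adaptive model to
  PH; ``nu = 0, eta = 0`` reduces it to RW. The learner's expectation of the
  reward SD before it can be estimated (trials 1 and 2) is ``sigma_init``.

All simulators return a full per-trial :class:`ModelTrace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ModelTrace",
    "scaling_factor",
    "update_running_sd",
    "running_sd_sequence",
    "simulate_rw",
    "simulate_ph",
    "simulate_adaptive_ph",
    "OMEGA_FLOOR",
    "SCALINGS",
]

#: Scaling-factor floor guarding against non-positive divisors in degenerate
#: parameter regions (e.g. nu > 1 with a small running SD).
OMEGA_FLOOR = 1e-3

SCALINGS = ("none", "linear", "log")


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector for the adaptive Pearce-Hall family.

    ``alpha1`` and ``sigma_init`` may be mappings keyed by SD level (the
    SD-specific initial-learning-rate variants and the per-condition initial
    expected SD). ``scaling='none'`` ignores ``nu``.
    """

    alpha1: float | Mapping[str, float]
    eta: float = 0.0
    nu: float = 0.0
    sigma_init: float | Mapping[str, float] | None = None
    scaling: str = "none"
    nu_fixed: bool = False
    nu_unconstrained: bool = False

    def __post_init__(self) -> None:
        if self.scaling not in SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        for a in self._values(self.alpha1):
            _check_unit("alpha1", a)
        _check_unit("eta", self.eta)
        if self.scaling != "none":
            if self.nu < 0:
                raise ValueError("nu must be non-negative")
            if not self.nu_unconstrained and self.nu > 1:
                raise ValueError("nu must lie in [0, 1] unless nu_unconstrained")
            if self.sigma_init is None:
                raise ValueError("adaptive scaling requires sigma_init")
            for s in self._values(self.sigma_init):
                if s <= 0:
                    raise ValueError("sigma_init must be positive")

    @staticmethod
    def _values(v):
        if v is None:
            return ()
        if isinstance(v, Mapping):
            return tuple(v.values())
        return (v,)

    def resolve(self, sd_level: str | None) -> tuple[float, float]:
        """Return (alpha1, sigma_init) for one SD level."""
        a = self.alpha1[sd_level] if isinstance(self.alpha1, Mapping) else self.alpha1
        s = self.sigma_init
        if isinstance(s, Mapping):
            s = s[sd_level]
        return a, (s if s is not None else 1.0)


@dataclass
class ModelTrace:
    """Per-trial record of a forward simulation (arrays of length T).

    ``predictions[t]`` is the model prediction stated *before* the reward of
    trial ``t`` is seen; ``final_prediction`` is the never-stated P[T+1].
    """

    predictions: np.ndarray
    deltas: np.ndarray
    alphas: np.ndarray
    sigmas: np.ndarray
    omegas: np.ndarray
    scaled_deltas: np.ndarray
    final_prediction: float = 0.0
    final_alpha: float = 0.0

    def __len__(self) -> int:
        return len(self.predictions)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "prediction_model": self.predictions,
                "delta": self.deltas,
                "alpha_t": self.alphas,
                "sigma_t": self.sigmas,
                "omega_t": self.omegas,
                "scaled_delta": self.scaled_deltas,
            }
        )


def scaling_factor(nu: float, sigma, scaling: str):
    """Prediction-error divisor ``omega = (1 - nu) + nu * f(sigma)``.

    ``f`` is identity for linear scaling and ``ln(max(sigma, 1))`` for log
    scaling (the floor keeps the log term non-negative); ``scaling='none'``
    returns 1. The result is floored at :data:`OMEGA_FLOOR`.
    """
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if scaling == "none":
        omega = np.ones_like(sigma)
    elif scaling == "linear":
        omega = (1.0 - nu) + nu * sigma
    else:
        omega = (1.0 - nu) + nu * np.log(np.maximum(sigma, 1.0))
    out = np.maximum(omega, OMEGA_FLOOR)
    return float(out) if out.ndim == 0 else out


def update_running_sd(rewards_seen: Sequence[float], sigma_init: float, t: int) -> float:
    """SD of rewards on trials 1..t; ``sigma_init`` while t <= 2.

    Sample (n-1 denominator) SD. ``t`` is 1-based and ``rewards_seen`` must
    contain at least ``t`` entries.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if t <= 2:
        return float(sigma_init)
    seg = np.asarray(rewards_seen[:t], dtype=float)
    return float(np.std(seg, ddof=1))


def running_sd_sequence(rewards: Sequence[float]) -> np.ndarray:
    """Running sample SD of rewards 1..t for every t; NaN for t <= 2.

    Precomputable once per reward sequence: only the first two entries depend
    on the fitted ``sigma_init``.
    """
    r = np.asarray(rewards, dtype=float)
    n = np.arange(1, len(r) + 1, dtype=float)
    csum = np.cumsum(r)
    csq = np.cumsum(r * r)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (csq - csum**2 / n) / (n - 1)
    out = np.sqrt(np.maximum(var, 0.0))
    out[:2] = np.nan
    return out


def predict_sequence(
    rewards: Sequence[float],
    alpha1: float,
    eta: float,
    nu: float,
    sigma_init: float,
    scaling: str,
    p1: float,
    sd_tail: np.ndarray | None = None,
) -> list[float]:
    """Fast scalar forward pass returning only the prediction sequence.

    ``sd_tail`` optionally supplies precomputed running SDs (used from trial 3
    on); otherwise they are accumulated via Welford's recurrence. Shared by
    :func:`simulate_adaptive_ph` and the least-squares objective.
    """
    P = float(p1)
    a = float(alpha1)
    preds: list[float] = []
    mean = 0.0
    m2 = 0.0
    none_scaling = scaling == "none"
    log_scaling = scaling == "log"
    for t, r in enumerate(rewards):
        preds.append(P)
        if none_scaling:
            omega = 1.0
        else:
            if t < 2:
                sigma = sigma_init
            elif sd_tail is not None:
                sigma = sd_tail[t]
            else:
                dmean = r - mean
                mean += dmean / (t + 1)
                m2 += dmean * (r - mean)
                sigma = math.sqrt(m2 / t) if m2 > 0 else 0.0
            if log_scaling:
                omega = (1.0 - nu) + nu * math.log(sigma if sigma > 1.0 else 1.0)
            else:
                omega = (1.0 - nu) + nu * sigma
            if omega < OMEGA_FLOOR:
                omega = OMEGA_FLOOR
        if not none_scaling and t < 2 and sd_tail is None:
            # keep Welford state in sync when sigma_init was used
            dmean = r - mean
            mean += dmean / (t + 1)
            m2 += dmean * (r - mean)
        delta = r - P
        scaled = delta / omega
        P = P + a * scaled
        s = abs(scaled) / 100.0
        a = eta * (s if s < 1.0 else 1.0) + (1.0 - eta) * a
    return preds


def _forward(
    rewards: Sequence[float],
    alpha1: float,
    eta: float,
    nu: float,
    sigma_init: float,
    scaling: str,
    p1: float,
    sd_tail: np.ndarray | None = None,
) -> ModelTrace:
    rewards = np.asarray(rewards, dtype=float)
    if rewards.size == 0:
        raise ValueError("rewards must be non-empty")
    T = rewards.size
    preds = np.empty(T)
    deltas = np.empty(T)
    alphas = np.empty(T)
    sigmas = np.full(T, np.nan)
    omegas = np.ones(T)
    scaled = np.empty(T)

    if scaling != "none":
        tail = running_sd_sequence(rewards) if sd_tail is None else np.asarray(sd_tail, float)
        sigmas[:] = tail
        sigmas[:2] = sigma_init

    P = float(p1)
    a = float(alpha1)
    for t in range(T):
        preds[t] = P
        alphas[t] = a
        if scaling != "none":
            # tolerant of a zero running SD (constant rewards); the strict
            # positivity check in scaling_factor applies to user input only
            sig = sigmas[t]
            if scaling == "log":
                om = (1.0 - nu) + nu * math.log(max(sig, 1.0))
            else:
                om = (1.0 - nu) + nu * sig
            omegas[t] = max(om, OMEGA_FLOOR)
        deltas[t] = rewards[t] - P
        scaled[t] = deltas[t] / omegas[t]
        P = P + a * scaled[t]
        s = min(abs(scaled[t]) / 100.0, 1.0)
        a = eta * s + (1.0 - eta) * a
    return ModelTrace(preds, deltas, alphas, sigmas, omegas, scaled, P, a)


def simulate_rw(rewards: Sequence[float], alpha: float, p1: float) -> ModelTrace:
    """Constant-learning-rate Rescorla-Wagner forward simulation."""
    _check_unit("alpha", alpha)
    return _forward(rewards, alpha, 0.0, 0.0, 1.0, "none", p1)


def simulate_ph(rewards: Sequence[float], alpha1: float, eta: float, p1: float) -> ModelTrace:
    """Pearce-Hall forward simulation with dynamic learning rate."""
    _check_unit("alpha1", alpha1)
    _check_unit("eta", eta)
    return _forward(rewards, alpha1, eta, 0.0, 1.0, "none", p1)


def simulate_adaptive_ph(
    rewards: Sequence[float],
    params: ModelParams,
    p1: float,
    sd_level: str | None = None,
) -> ModelTrace:
    """Variance-adaptive Pearce-Hall forward simulation.

    The prediction update divides the error by ``omega[t]`` derived from the
    running reward SD; the learning-rate update uses the same scaled error.
    With ``scaling='none'`` this is plain PH (and RW when ``eta = 0``).
    """
    alpha1, sigma_init = params.resolve(sd_level)
    return _forward(rewards, alpha1, params.eta, params.nu, sigma_init, params.scaling, p1)
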