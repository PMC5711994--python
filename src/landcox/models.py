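"""Model specifications shared across the package.

The central object is a time-dependent Cox model

    h(t | X-bar(t)) = h0(t) * exp(beta(t) * X(t)),

where the hazard depends on the covariate history only through its current
value.  For a dichotomous covariate the joint law of (X(t), T) is an
illness-death multi-state model whose death hazards are tied to the Cox
model; for a continuous covariate it is a Gaussian process (see
:mod:`landcox.ou_theory`).

Hazard and coefficient functions are plain callables ``time -> value``,
vectorised over numpy arrays.  Constant and piecewise-constant functions can
be specified in YAML/JSON configs as a number or a list of
``[breakpoint, value]`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import yaml

__all__ = [
    "CoxTDModel",
    "IllnessDeathRates",
    "OUParams",
    "constant",
    "piecewise_constant",
    "as_rate_function",
    "model_from_config",
    "rates_from_config",
    "InvalidModelError",
    "DegenerateConditioningError",
    "DegenerateWeightsError",
]

RateFunction = Callable[[np.ndarray], np.ndarray]


class InvalidModelError(ValueError):
    """A model or rate specification is unusable (negative/nonfinite rates,
    or an inconsistent model/rates pairing)."""


class DegenerateConditioningError(ValueError):
    """A conditional probability is requested on an event of probability 0
    (e.g. prevalence among survivors when nobody survives)."""


class DegenerateWeightsError(ValueError):
    """A weighted average is requested with identically-zero weights."""


def constant(value: float) -> RateFunction:
    """Return ``t -> value`` vectorised over arrays."""
    value = float(value)

    def f(t):
        return np.full_like(np.asarray(t, dtype=float), value)

    f.__name__ = f"constant_{value}"
    return f


def piecewise_constant(breakpoints, values) -> RateFunction:
    """Right-continuous step function.

    ``breakpoints`` are the left endpoints of each piece (the first must be
    0); ``values`` the value on each piece.
    """
    bp = np.asarray(breakpoints, dtype=float)
    val = np.asarray(values, dtype=float)
    if bp.ndim != 1 or bp.shape != val.shape:
        raise InvalidModelError("breakpoints and values must be 1-d and equal length")
    if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
        raise InvalidModelError("breakpoints must start at 0 and increase strictly")

    def f(t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, len(bp) - 1)
        return val[idx]

    return f


def as_rate_function(spec: Union[float, int, RateFunction, list]) -> RateFunction:
    """Coerce a config entry (number, [[breakpoint, value], ...] list, or
    callable) to a vectorised time function."""
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return constant(spec)
    pairs = list(spec)
    bp = [p[0] for p in pairs]
    vals = [p[1] for p in pairs]
    return piecewise_constant(bp, vals)


@dataclass(frozen=True)
class CoxTDModel:
    """True time-dependent Cox model: baseline hazard ``h0`` (per unit time)
    and log hazard ratio ``beta`` (dimensionless), both functions of time."""

    h0: RateFunction
    beta: RateFunction

    def __post_init__(self):
        grid = np.linspace(0.0, 1.0, 5)
        h = np.asarray(self.h0(grid), dtype=float)
        b = np.asarray(self.beta(grid), dtype=float)
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(b))):
            raise InvalidModelError("h0 and beta must evaluate to finite values")
        if np.any(h < 0):
            raise InvalidModelError("baseline hazard must be nonnegative")

    @classmethod
    def from_constants(cls, h0: float, beta: float) -> "CoxTDModel":
        return cls(h0=constant(h0), beta=constant(beta))


@dataclass(frozen=True)
class IllnessDeathRates:
    """The four transition hazards of the illness-death model.

    States: 0 = initial (covariate 0), 1 = response/illness (covariate 1),
    2 = death (absorbing).  ``lambda10`` identically 0 gives the irreversible
    model.  When tied to a :class:`CoxTDModel`, ``lambda02 = h0`` and
    ``lambda12 = h0 * exp(beta)``.
    """

    lambda01: RateFunction
    lambda10: RateFunction
    lambda02: RateFunction
    lambda12: RateFunction

    @classmethod
    def from_cox_model(
        cls, model: CoxTDModel, lambda01, lambda10=0.0
    ) -> "IllnessDeathRates":
        """Build rates consistent with a Cox model for the death transitions."""
        l01 = as_rate_function(lambda01)
        l10 = as_rate_function(lambda10)

        def l02(t):
            return np.asarray(model.h0(t), dtype=float)

        def l12(t):
            t = np.asarray(t, dtype=float)
            return np.asarray(model.h0(t), dtype=float) * np.exp(
                np.asarray(model.beta(t), dtype=float)
            )

        return cls(lambda01=l01, lambda10=l10, lambda02=l02, lambda12=l12)

    def is_irreversible(self, t_max: float = 50.0, n: int = 201) -> bool:
        grid = np.linspace(0.0, t_max, n)
        return bool(np.all(np.asarray(self.lambda10(grid)) == 0.0))

    def validate_consistent(self, model: CoxTDModel, t_max: float = 20.0) -> None:
        """Check lambda02 = h0 and lambda12 = h0*exp(beta) on a grid."""
        grid = np.linspace(0.0, t_max, 101)
        h0 = np.asarray(model.h0(grid), dtype=float)
        eb = np.exp(np.asarray(model.beta(grid), dtype=float))
        if not np.allclose(self.lambda02(grid), h0, rtol=1e-8, atol=1e-12):
            raise InvalidModelError("lambda02 does not match the model's h0")
        if not np.allclose(self.lambda12(grid), h0 * eb, rtol=1e-8, atol=1e-12):
            raise InvalidModelError("lambda12 does not match h0 * exp(beta)")


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck-plus-random-intercept covariate process.

    X_i(t) = mu(t) + b_i + X_i*(t), with b_i ~ N(0, omega^2) a stable person
    effect and X* a mean-zero OU process dX* = -theta X* dt + sigma dW.

    User-facing parameters are the total variance ``sigma_tot_sq``
    (= omega^2 + sigma^2/(2 theta)), the intraclass correlation ``rho_ic``
    (= omega^2 / sigma_tot_sq, the share of variance from the person effect
    and the asymptote of the lag correlation) and the mean-reversal rate
    ``theta``; omega^2 and the diffusion sigma^2 are derived.
    """

    sigma_tot_sq: float
    rho_ic: float
    theta: float
    mu: RateFunction = field(default_factory=lambda: constant(0.0))

    def __post_init__(self):
        if not self.sigma_tot_sq > 0:
            raise InvalidModelError("sigma_tot_sq must be > 0")
        if not 0.0 <= self.rho_ic <= 1.0:
            raise InvalidModelError("rho_ic must lie in [0, 1]")
        if not self.theta > 0:
            raise InvalidModelError("theta must be > 0")

    @property
    def omega_sq(self) -> float:
        """Person-effect variance omega^2 = rho * sigma_tot^2."""
        return self.rho_ic * self.sigma_tot_sq

    @property
    def sigma_sq(self) -> float:
        """Diffusion variance sigma^2 = 2 theta (1 - rho) sigma_tot^2, chosen
        so that omega^2 + sigma^2/(2 theta) = sigma_tot^2 exactly."""
        return 2.0 * self.theta * (1.0 - self.rho_ic) * self.sigma_tot_sq


def model_from_config(cfg: dict) -> CoxTDModel:
    """Build a CoxTDModel from a config mapping with keys ``h0`` and ``beta``
    (numbers or [breakpoint, value] lists)."""
    return CoxTDModel(h0=as_rate_function(cfg["h0"]), beta=as_rate_function(cfg["beta"]))


def rates_from_config(cfg: dict) -> IllnessDeathRates:
    """Build IllnessDeathRates from a config mapping with keys lambda01,
    lambda10 (optional, default 0), lambda02, lambda12."""
    return IllnessDeathRates(
        lambda01=as_rate_function(cfg["lambda01"]),
        lambda10=as_rate_function(cfg.get("lambda10", 0.0)),
        lambda02=as_rate_function(cfg["lambda02"]),
        lambda12=as_rate_function(cfg["lambda12"]),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
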