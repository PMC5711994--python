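"""Exact landmark-coefficient theory for dichotomous time-dependent covariates.

The covariate is the state of an illness-death multi-state model (states
0 = no response, 1 = response, 2 = death, absorbing); death hazards are tied
to the time-dependent Cox model, ``lambda02 = h0`` and
``lambda12 = h0 * exp(beta)``.  Under the Markov assumption the transition
probabilities P_gh(s, t) solve the Kolmogorov forward equations

    dP(s, u)/du = P(s, u) Q(u),   P(s, s) = I,

with generator Q built from the four transition hazards.  From these we get

* the conditional prevalences pi_g1(s, t) = P_g1 / (P_g0 + P_g1), the
  probability of being in response at t given state g at the landmark s and
  alive at t;
* the time-varying coefficient of the landmark model,

    exp(beta_LM(t|s)) = (pi_10 + e^beta(t) pi_11) / (pi_00 + e^beta(t) pi_01),

  which reduces in the irreversible case (pi_11 = 1) to
  beta(t) - log(1 + (e^beta(t) - 1) pi_01(s, t));
* its derivative in t at t = s,
  beta'(s) - (e^beta(s) - 1) {lambda01(s) + lambda10(s) e^{-beta(s)}};
* the weighted time-average beta*_LM(s) that a (misspecified)
  proportional-hazards landmark fit approximately estimates, with weight
  var(X | T = t) h(t) S(t) C(t) computed for the landmark population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .models import (
    CoxTDModel,
    DegenerateConditioningError,
    DegenerateWeightsError,
    IllnessDeathRates,
    InvalidModelError,
    constant,
)

__all__ = [
    "TransitionMatrix",
    "PrevalencePair",
    "BetaStarInputs",
    "transition_probability_matrix",
    "transition_probabilities",
    "prevalence",
    "landmark_coef_general",
    "landmark_coef_irreversible",
    "landmark_coef_slope_at_s",
    "beta_star",
    "uniform_censoring_survival",
    "default_horizon",
    "theory_curve",
]

# tight tolerances: occupation probabilities near 0/1 control log-ratio output
_ATOL = 1e-10
_RTOL = 1e-8


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 matrix of P_gh(s, t) over states {0, 1, 2}."""

    s: float
    t: float
    P: np.ndarray


@dataclass(frozen=True)
class PrevalencePair:
    """pi_01(s, t) and pi_11(s, t); pi_g0 = 1 - pi_g1."""

    pi01: float
    pi11: float

    @property
    def pi00(self) -> float:
        return 1.0 - self.pi01

    @property
    def pi10(self) -> float:
        return 1.0 - self.pi11


def _generator(rates: IllnessDeathRates, u) -> np.ndarray:
    """Generator matrix Q(u); shape (3, 3) for scalar u."""
    l01 = float(np.asarray(rates.lambda01(u)))
    l10 = float(np.asarray(rates.lambda10(u)))
    l02 = float(np.asarray(rates.lambda02(u)))
    l12 = float(np.asarray(rates.lambda12(u)))
    for name, val in (("lambda01", l01), ("lambda10", l10),
                      ("lambda02", l02), ("lambda12", l12)):
        if not np.isfinite(val):
            raise InvalidModelError(f"{name} evaluated to a nonfinite value at t={u}")
        if val < 0:
            raise InvalidModelError(f"{name} is negative at t={u}")
    return np.array(
        [
            [-(l01 + l02), l01, l02],
            [l10, -(l10 + l12), l12],
            [0.0, 0.0, 0.0],
        ]
    )


def transition_probabilities(
    rates: IllnessDeathRates, s: float, t_grid: np.ndarray
) -> np.ndarray:
    """Solve the forward equations from s, returning P(s, t) for each t in
    ``t_grid`` (nondecreasing, t_grid[0] >= s).  Shape (len(t_grid), 3, 3).
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size == 0:
        return np.empty((0, 3, 3))
    if np.any(t_grid < s):
        raise ValueError("all evaluation times must satisfy t >= s")
    t_end = float(t_grid[-1])
    if t_end == s:
        return np.broadcast_to(np.eye(3), (t_grid.size, 3, 3)).copy()

    def rhs(u, p):
        P = p.reshape(3, 3)
        return (P @ _generator(rates, u)).ravel()

    sol = solve_ivp(
        rhs,
        (s, t_end),
        np.eye(3).ravel(),
        t_eval=t_grid,
        method="DOP853",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:  # pragma: no cover - solver failure is pathological
        raise RuntimeError(f"forward-equation solver failed: {sol.message}")
    P = sol.y.T.reshape(-1, 3, 3)
    # clip tiny negative round-off, keep rows summing to 1
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_probability_matrix(
    rates: IllnessDeathRates, s: float, t: float
) -> TransitionMatrix:
    """P_gh(s, t) by the Kolmogorov forward equations."""
    if t < s or s < 0:
        raise ValueError(f"need 0 <= s <= t, got s={s}, t={t}")
    P = transition_probabilities(rates, s, np.array([t]))[0]
    return TransitionMatrix(s=float(s), t=float(t), P=P)


def _prevalences_from_P(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pi_01 and pi_11 from stacked P(s, t) matrices, shape (m, 3, 3)."""
    alive0 = P[:, 0, 0] + P[:, 0, 1]
    alive1 = P[:, 1, 0] + P[:, 1, 1]
    if np.any(alive0 <= 0.0) or np.any(alive1 <= 0.0):
        raise DegenerateConditioningError(
            "no survivors from some starting state: prevalence undefined"
        )
    return P[:, 0, 1] / alive0, P[:, 1, 1] / alive1


def prevalence(rates: IllnessDeathRates, s: float, t: float) -> PrevalencePair:
    """Conditional prevalences pi_01(s, t), pi_11(s, t) among survivors at t."""
    P = transition_probability_matrix(rates, s, t).P
    pi01, pi11 = _prevalences_from_P(P[None, :, :])
    return PrevalencePair(pi01=float(pi01[0]), pi11=float(pi11[0]))


def landmark_coef_general(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    s: float,
    t,
    *,
    check_consistency: bool = False,
):
    """beta_LM(t|s) for a possibly reversible illness-death covariate.

    log of (pi_10 + e^beta(t) pi_11) / (pi_00 + e^beta(t) pi_01); always
    between -|beta(t)| and |beta(t)|.  Vectorised over ``t``.
    """
    if check_consistency:
        rates.validate_consistent(model)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(t_arr)
    P = transition_probabilities(rates, s, t_arr[order])
    pi01 = np.empty_like(t_arr)
    pi11 = np.empty_like(t_arr)
    pi01[order], pi11[order] = _prevalences_from_P(P)
    eb = np.exp(np.asarray(model.beta(t_arr), dtype=float))
    out = np.log(((1.0 - pi11) + eb * pi11) / ((1.0 - pi01) + eb * pi01))
    return out if np.ndim(t) else float(out[0])


def landmark_coef_irreversible(
    model: CoxTDModel, rates: IllnessDeathRates, s: float, t
):
    """beta_LM(t|s) = beta(t) - log(1 + (e^beta(t) - 1) pi_01(s, t)) for the
    irreversible model (no 1 -> 0 transitions).  Vectorised over ``t``."""
    if not rates.is_irreversible():
        raise InvalidModelError(
            "irreversible formula requires lambda10 identically 0"
        )
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(t_arr)
    P = transition_probabilities(rates, s, t_arr[order])
    pi01 = np.empty_like(t_arr)
    pi01[order], _ = _prevalences_from_P(P)
    b = np.asarray(model.beta(t_arr), dtype=float)
    out = b - np.log1p(np.expm1(b) * pi01)
    return out if np.ndim(t) else float(out[0])


def landmark_coef_slope_at_s(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    s: float,
    *,
    step: Optional[float] = None,
) -> float:
    """d/dt beta_LM(t|s) at t = s:

        beta'(s) - (e^beta(s) - 1) {lambda01(s) + lambda10(s) e^{-beta(s)}}

    beta'(s) is a central finite difference with configurable step
    (default 1e-5 * max(1, s))."""
    if step is None:
        step = 1e-5 * max(1.0, abs(s))
    lo = max(s - step, 0.0)
    bprime = (float(model.beta(s + step)) - float(model.beta(lo))) / (s + step - lo)
    b = float(np.asarray(model.beta(s)))
    l01 = float(np.asarray(rates.lambda01(s)))
    l10 = float(np.asarray(rates.lambda10(s)))
    return bprime - np.expm1(b) * (l01 + l10 * np.exp(-b))


def uniform_censoring_survival(lo: float, hi: float) -> Callable:
    """Survival function of a Uniform(lo, hi) censoring time:
    1 before lo, (hi - t)/(hi - lo) on [lo, hi], 0 after."""
    if not lo < hi:
        raise ValueError("need lo < hi")

    def C(t):
        t = np.asarray(t, dtype=float)
        return np.clip((hi - t) / (hi - lo), 0.0, 1.0)

    return C


def default_horizon(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    q: float = 0.999,
    t_max: float = 500.0,
) -> float:
    """Quantile ``q`` of the event-time distribution (start: state 0 at 0),
    used as the default integration horizon for :func:`beta_star`."""
    grid = np.linspace(0.0, t_max, 2001)
    P = transition_probabilities(rates, 0.0, grid)
    surv = P[:, 0, 0] + P[:, 0, 1]
    below = np.nonzero(surv <= 1.0 - q)[0]
    return float(grid[below[0]]) if below.size else float(t_max)


@dataclass(frozen=True)
class BetaStarInputs:
    """Inputs of the weighted-average coefficient beta*_LM(s).

    ``censoring_surv`` is the survival function C(t) of the censoring time
    (default: no censoring); ``grid`` a strictly increasing grid spanning
    [s, t_hor] (default: 2000 uniform points).
    """

    s: float
    t_hor: float
    censoring_surv: Callable = field(default_factory=lambda: constant(1.0))
    grid: Optional[np.ndarray] = None

    def resolved_grid(self) -> np.ndarray:
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
                raise ValueError("grid must be strictly increasing, length >= 2")
            return g
        return np.linspace(self.s, self.t_hor, 2000)


def beta_star(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    inputs: BetaStarInputs,
    *,
    covariate: str = "landmark",
) -> float:
    """Weighted time-average of beta_LM(t|s) approximating the coefficient a
    proportional-hazards landmark fit estimates:

        beta*_LM(s) = int beta_LM(t|s) w(t) dt / int w(t) dt,
        w(t) = var(X | T = t) h(t) S(t) C(t),

    where h, S and the variance refer to the landmark population (survivors
    at s, mixture over X(s) with shares from state occupation starting in
    state 0 at time 0).

    ``covariate="landmark"`` (default) takes var(X(s) | T = t), the variance
    of the covariate the misspecified model actually fits;
    ``covariate="current"`` takes var(X(t) | T = t) instead.
    """
    if covariate not in ("landmark", "current"):
        raise ValueError("covariate must be 'landmark' or 'current'")
    s = float(inputs.s)
    grid = inputs.resolved_grid()
    if not np.isclose(grid[0], s):
        raise ValueError("grid must start at the landmark time s")

    # landmark-population mixture shares from occupation at s (start 0 at 0)
    P0s = transition_probabilities(rates, 0.0, np.array([s]))[0]
    alive = P0s[0, 0] + P0s[0, 1]
    if alive <= 0:
        raise DegenerateConditioningError("nobody survives to the landmark s")
    q1 = P0s[0, 1] / alive
    q0 = 1.0 - q1

    P = transition_probabilities(rates, s, grid)
    S0 = P[:, 0, 0] + P[:, 0, 1]
    S1 = P[:, 1, 0] + P[:, 1, 1]
    pi01 = P[:, 0, 1] / np.maximum(S0, 1e-300)
    pi11 = P[:, 1, 1] / np.maximum(S1, 1e-300)
    eb = np.exp(np.asarray(model.beta(grid), dtype=float))
    h0 = np.asarray(model.h0(grid), dtype=float)
    hlm0 = h0 * ((1.0 - pi01) + eb * pi01)   # hazard given X(s)=0
    hlm1 = h0 * ((1.0 - pi11) + eb * pi11)   # hazard given X(s)=1
    beta_lm = np.log(hlm1 / hlm0)

    f0 = S0 * hlm0
    f1 = S1 * hlm1
    f = q0 * f0 + q1 * f1                    # marginal event density
    S = q0 * S0 + q1 * S1

    if covariate == "landmark":
        p = np.divide(q1 * f1, f, out=np.zeros_like(f), where=f > 0)
    else:
        # probability the failure at t occurs from state 1 (current covariate)
        l12 = np.asarray(rates.lambda12(grid), dtype=float)
        from1 = l12 * (q0 * P[:, 0, 1] + q1 * P[:, 1, 1])
        p = np.divide(from1, f, out=np.zeros_like(f), where=f > 0)
    var = p * (1.0 - p)

    C = np.asarray(inputs.censoring_surv(grid), dtype=float)
    w = var * f * C
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise DegenerateWeightsError(
            "total weight is zero on [s, t_hor] (is C identically 0 there?)"
        )
    return float(np.trapezoid(beta_lm * w, grid) / denom)


def landmark_ph_limit(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    inputs: BetaStarInputs,
) -> float:
    """Exact large-sample limit of the misspecified proportional-hazards
    landmark fit: the root of the population partial-likelihood score

        int [ q1 S1(t) h1(t) - f(t) m(b, t) ] C(t) dt = 0,
        m(b, t) = q1 S1(t) e^b / (q0 S0(t) + q1 S1(t) e^b),

    with the same landmark-population ingredients as :func:`beta_star`.
    The weighted-average formula beta_star approximates this root; their
    difference quantifies the approximation error of the weighted average.
    """
    from scipy.optimize import brentq

    s = float(inputs.s)
    grid = inputs.resolved_grid()
    P0s = transition_probabilities(rates, 0.0, np.array([s]))[0]
    alive = P0s[0, 0] + P0s[0, 1]
    if alive <= 0:
        raise DegenerateConditioningError("nobody survives to the landmark s")
    q1 = P0s[0, 1] / alive
    q0 = 1.0 - q1

    P = transition_probabilities(rates, s, grid)
    S0 = P[:, 0, 0] + P[:, 0, 1]
    S1 = P[:, 1, 0] + P[:, 1, 1]
    pi01 = P[:, 0, 1] / np.maximum(S0, 1e-300)
    pi11 = P[:, 1, 1] / np.maximum(S1, 1e-300)
    eb = np.exp(np.asarray(model.beta(grid), dtype=float))
    h0 = np.asarray(model.h0(grid), dtype=float)
    hlm0 = h0 * ((1.0 - pi01) + eb * pi01)
    hlm1 = h0 * ((1.0 - pi11) + eb * pi11)
    C = np.asarray(inputs.censoring_surv(grid), dtype=float)
    f1 = q1 * S1 * hlm1
    f = q0 * S0 * hlm0 + f1
    if np.trapezoid(f * C, grid) <= 0:
        raise DegenerateWeightsError("no events on [s, t_hor] under C(t)")

    def score(b):
        m = q1 * S1 * np.exp(b) / (q0 * S0 + q1 * S1 * np.exp(b))
        return float(np.trapezoid((f1 - f * m) * C, grid))

    bmax = float(np.max(np.abs(np.asarray(model.beta(grid))))) + 1.0
    return float(brentq(score, -bmax, bmax, xtol=1e-12))


def theory_curve(
    model: CoxTDModel,
    rates: IllnessDeathRates,
    s: float,
    t_grid: np.ndarray,
):
    """Convenience table of (s, t, beta_lm, pi01, pi11) for plotting/export."""
    import pandas as pd

    t_grid = np.asarray(t_grid, dtype=float)
    P = transition_probabilities(rates, s, t_grid)
    pi01, pi11 = _prevalences_from_P(P)
    eb = np.exp(np.asarray(model.beta(t_grid), dtype=float))
    beta_lm = np.log(((1.0 - pi11) + eb * pi11) / ((1.0 - pi01) + eb * pi01))
    return pd.DataFrame(
        {"s": s, "t": t_grid, "beta_lm": beta_lm, "pi01": pi01, "pi11": pi11}
    )
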