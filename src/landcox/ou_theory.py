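"""Approximate landmark-coefficient theory for a continuous Gaussian covariate.

The covariate follows an Ornstein-Uhlenbeck process plus a random person
intercept (see :class:`landcox.models.OUParams`), so (X(s), X(t)) is
bivariate normal with lag correlation

    rho(s, t) = rho + (1 - rho) exp(-theta |t - s|),

decreasing from 1 at zero lag to the intraclass correlation rho.  Ignoring
the selection effect of having survived to t, the conditional expectation
entering the landmark hazard is the Gaussian moment generating function of
X(t) | X(s) evaluated at beta(t):

    log E[e^{beta(t) X(t)} | T >= t, X(s)]
        ~= beta(t) mu(t | X(s)) + (1/2) beta(t)^2 sigma_tot^2 (1 - rho(s,t)^2),

and differentiating its logarithm in X(s) gives the attenuation relation

    beta_LM(t | s) ~= beta(t) rho(s, t).

These are stated approximations: survival selection is deliberately not
corrected for here (the Monte Carlo machinery in :mod:`landcox.simulate`
quantifies its effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CoxTDModel, OUParams

__all__ = [
    "OUConditional",
    "ou_correlation",
    "ou_covariance",
    "ou_conditional_moments",
    "landmark_log_factor",
    "landmark_coef_ou",
    "ou_theory_curve",
]


@dataclass(frozen=True)
class OUConditional:
    """Conditional law of X(t) given X(s) = x_s: normal with this mean and
    variance; ``corr`` is the lag correlation rho(s, t)."""

    mean: float
    variance: float
    corr: float


def ou_correlation(params: OUParams, s, t):
    """Lag correlation rho + (1 - rho) exp(-theta |t - s|); symmetric in
    (s, t), equal to 1 at zero lag and to rho as the lag grows."""
    lag = np.abs(np.asarray(t, dtype=float) - np.asarray(s, dtype=float))
    out = params.rho_ic + (1.0 - params.rho_ic) * np.exp(-params.theta * lag)
    return float(out) if out.ndim == 0 else out


def ou_covariance(params: OUParams, s, t):
    """cov(X(s), X(t)) = omega^2 + (sigma^2 / 2 theta) exp(-theta |t - s|)
    = sigma_tot^2 * rho(s, t)."""
    return params.sigma_tot_sq * ou_correlation(params, s, t)


def ou_conditional_moments(
    params: OUParams, s: float, x_s: float, t: float
) -> OUConditional:
    """Moments of X(t) | X(s) = x_s:

    mean = mu(t) + rho(s, t) (x_s - mu(s)),
    variance = sigma_tot^2 (1 - rho(s, t)^2)."""
    r = ou_correlation(params, s, t)
    mu_s = float(np.asarray(params.mu(s)))
    mu_t = float(np.asarray(params.mu(t)))
    return OUConditional(
        mean=mu_t + r * (x_s - mu_s),
        variance=params.sigma_tot_sq * (1.0 - r * r),
        corr=r,
    )


def landmark_log_factor(
    params: OUParams, model: CoxTDModel, s: float, x_s: float, t
):
    """log of the (approximate) conditional expectation E[e^{beta(t) X(t)} |
    T >= t, X(s) = x_s]:

        beta(t) mu(t|x_s) + (1/2) beta(t)^2 sigma_tot^2 (1 - rho(s,t)^2).

    Exact Gaussian MGF identity when survival selection is ignored.
    Vectorised over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    r = params.rho_ic + (1.0 - params.rho_ic) * np.exp(
        -params.theta * np.abs(t_arr - s)
    )
    mu_s = float(np.asarray(params.mu(s)))
    mu_t = np.asarray(params.mu(t_arr), dtype=float)
    b = np.asarray(model.beta(t_arr), dtype=float)
    cond_mean = mu_t + r * (x_s - mu_s)
    out = b * cond_mean + 0.5 * b * b * params.sigma_tot_sq * (1.0 - r * r)
    return float(out) if out.ndim == 0 else out


def landmark_coef_ou(params: OUParams, model: CoxTDModel, s: float, t):
    """Attenuated landmark coefficient beta(t) * rho(s, t) (per covariate
    unit); equals beta(s) at t = s and tends to beta * rho_ic as t grows.
    Vectorised over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    b = np.asarray(model.beta(t_arr), dtype=float)
    out = b * ou_correlation(params, s, t_arr)
    return float(out) if out.ndim == 0 else out


def ou_theory_curve(
    params: OUParams, model: CoxTDModel, s: float, x_values, t_grid
):
    """Table of (s, t, x_s, log_factor, beta_lm) for export/plotting."""
    import pandas as pd

    frames = []
    t_grid = np.asarray(t_grid, dtype=float)
    blm = landmark_coef_ou(params, model, s, t_grid)
    for x in x_values:
        frames.append(
            pd.DataFrame(
                {
                    "s": s,
                    "t": t_grid,
                    "x_s": x,
                    "log_factor": landmark_log_factor(params, model, s, x, t_grid),
                    "beta_lm": blm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
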