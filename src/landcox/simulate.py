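"""Simulators for the two covariate-survival designs, plus the Monte Carlo
conditional-expectation estimator for the continuous case.

Dichotomous design: subject-level illness-death histories with exponential
(or piecewise-exponential via constant-rate restriction) transitions, sampled
exactly by inversion of competing exponentials -- no Euler discretisation
error enters the simulation study.

Continuous design: Ornstein-Uhlenbeck-plus-intercept covariate paths evolved
by Euler-Maruyama on a grid of step ``dt``, with death decided at each step
by a Bernoulli coin with probability h0(t) exp(beta(t) X(t)) dt.

Reproducibility: the generators use a counter-based Philox bit generator and
draw in fixed-size subject blocks, so with the same seed the first n1
subjects are identical for any requested n >= n1 (no reshuffling when a
study is enlarged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import CoxTDModel, InvalidModelError, OUParams

__all__ = [
    "SimConfig",
    "SubjectRecord",
    "OUPaths",
    "StepSizeError",
    "InsufficientPathsError",
    "simulate_illness_death",
    "simulate_ou_survival",
    "mc_conditional_expectation",
    "covariate_at",
    "subjects_to_csv",
    "paths_to_csv",
]

_CHUNK = 4096  # fixed subject-block size; keeps draws stable under n growth


class StepSizeError(ValueError):
    """The per-step death probability reached 1; reduce dt."""


class InsufficientPathsError(ValueError):
    """No simulated paths satisfy a conditioning window."""


@dataclass(frozen=True)
class SimConfig:
    """Common simulation settings.

    n: number of subjects; seed: master seed; dt: Euler step for the OU
    design; horizon: administrative censoring time (None = none);
    censoring: None or (lo, hi) for an independent Uniform(lo, hi)
    censoring time; dX: half-width of the conditioning window used by
    :func:`mc_conditional_expectation`.
    """

    n: int
    seed: int
    dt: float = 0.01
    horizon: Optional[float] = None
    censoring: Optional[tuple] = None
    dX: float = 0.1

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.censoring is not None:
            lo, hi = self.censoring
            if not lo < hi:
                raise ValueError("uniform censoring needs lo < hi")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject of the dichotomous design (row schema of the subjects
    frame): 0 -> 1 response time (None if never observed), optional later
    jump times in the reversible model, and the follow-up endpoint."""

    id: int
    response_time: Optional[float]
    event_time: float
    status: int
    censor_applied: bool
    back_times: Optional[Sequence[float]] = None


def _chunked_uniforms(seed: int, n: int, k: int) -> np.ndarray:
    """(n, k) uniforms drawn in fixed blocks of _CHUNK subjects from a
    Philox stream keyed by ``seed``; rows are independent of the total n."""
    gen = np.random.Generator(np.random.Philox(key=np.uint64(seed)))
    blocks = []
    done = 0
    while done < n:
        blocks.append(gen.random((_CHUNK, k)))
        done += _CHUNK
    return np.vstack(blocks)[:n]


def simulate_illness_death(
    config: SimConfig,
    lambda01: float,
    lambda02: float,
    beta: float,
    lambda10: float = 0.0,
) -> pd.DataFrame:
    """Sample ``config.n`` illness-death histories with constant rates.

    From state 0 the sojourn ends at min(Exp(lambda01), Exp(lambda02)); death
    from state 1 has rate lambda02 * exp(beta); the reversible model
    (lambda10 > 0) alternates states until death.  Censoring (uniform and/or
    administrative horizon) is applied independently.

    Returns a frame with columns id, response_time (NaN if no observed
    0 -> 1 jump), event_time, status (1 = death), censor_applied, and, for
    the reversible model, jumps (array of alternating jump times).
    """
    for name, v in (("lambda01", lambda01), ("lambda02", lambda02),
                    ("lambda10", lambda10)):
        if v < 0 or not np.isfinite(v):
            raise InvalidModelError(f"{name} must be a finite nonnegative rate")
    n = config.n
    lam12 = lambda02 * np.exp(beta)

    if lambda10 == 0.0:
        u = _chunked_uniforms(config.seed, n, 4)
        with np.errstate(divide="ignore"):
            t01 = -np.log(u[:, 0]) / lambda01 if lambda01 > 0 else np.full(n, np.inf)
            t02 = -np.log(u[:, 1]) / lambda02 if lambda02 > 0 else np.full(n, np.inf)
            t12 = -np.log(u[:, 2]) / lam12 if lam12 > 0 else np.full(n, np.inf)
        responded = t01 < t02
        death = np.where(responded, t01 + t12, t02)
        response = np.where(responded, t01, np.inf)
        jumps = None
    else:
        # reversible: alternate 0 <-> 1 until death; per-subject loop
        gen = np.random.Generator(np.random.Philox(key=np.uint64(config.seed)))
        death = np.empty(n)
        response = np.full(n, np.inf)
        jumps = []
        for i in range(n):
            t, state, jl = 0.0, 0, []
            while True:
                if state == 0:
                    out_rate = lambda01 + lambda02
                    t += gen.exponential(1.0 / out_rate) if out_rate > 0 else np.inf
                    if not np.isfinite(t) or gen.random() < lambda02 / out_rate:
                        break
                    state = 1
                else:
                    out_rate = lambda10 + lam12
                    t += gen.exponential(1.0 / out_rate)
                    if gen.random() < lam12 / out_rate:
                        break
                    state = 0
                jl.append(t)
            death[i] = t
            if jl:
                response[i] = jl[0]
            jumps.append(np.asarray(jl))
        u = _chunked_uniforms(config.seed + 1, n, 1)  # censoring draws

    if config.censoring is not None:
        lo, hi = config.censoring
        cens = lo + (hi - lo) * (u[:, 3] if lambda10 == 0.0 else u[:, 0])
    else:
        cens = np.full(n, np.inf)
    if config.horizon is not None:
        cens = np.minimum(cens, config.horizon)

    event_time = np.minimum(death, cens)
    status = (death <= cens).astype(int)
    observed_response = np.where(response < event_time, response, np.nan)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "response_time": observed_response,
            "event_time": event_time,
            "status": status,
            "censor_applied": status == 0,
        }
    )
    if jumps is not None:
        df["jumps"] = [j[j < et] for j, et in zip(jumps, event_time)]
    return df


def covariate_at(subjects: pd.DataFrame, s: float) -> np.ndarray:
    """Dichotomous covariate value X(s) per subject (0/1).

    Irreversible: 1 iff the response occurred at or before s.  Reversible:
    parity of the number of jumps at or before s."""
    if "jumps" in subjects.columns:
        return np.array(
            [int(np.sum(j <= s) % 2) for j in subjects["jumps"]], dtype=int
        )
    rt = subjects["response_time"].to_numpy()
    return ((~np.isnan(rt)) & (rt <= s)).astype(int)


@dataclass
class OUPaths:
    """A batch of OU covariate paths on a common grid.

    values[i, k] is X_i(grid[k]) = mu + b_i + X*_i, NaN after subject i's
    event time; status 1 = death, 0 = administratively censored at the
    horizon.
    """

    grid: np.ndarray
    values: np.ndarray
    b: np.ndarray
    event_time: np.ndarray
    status: np.ndarray
    params: OUParams = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def value_at(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.grid - t)))
        if abs(self.grid[k] - t) > 1e-9 + 1e-6 * abs(t):
            raise ValueError(f"time {t} is not on the simulation grid")
        return self.values[:, k]


def _simulate_ou_batch(
    seed: int,
    n: int,
    config: SimConfig,
    params: OUParams,
    model: CoxTDModel,
    paper_literal_init: bool,
    paper_literal_step: bool,
) -> OUPaths:
    dt = config.dt
    horizon = config.horizon if config.horizon is not None else 10.0
    m = int(round(horizon / dt)) + 1
    grid = np.arange(m) * dt
    omega = np.sqrt(params.omega_sq)
    sigma = np.sqrt(params.sigma_sq)
    stat_sd = np.sqrt(params.sigma_sq / (2.0 * params.theta))
    mu = np.asarray(params.mu(grid), dtype=float)
    h0 = np.asarray(model.h0(grid), dtype=float)
    beta = np.asarray(model.beta(grid), dtype=float)
    incr_scale = sigma * (dt if paper_literal_step else np.sqrt(dt))

    from scipy.special import ndtri

    # per-subject draw layout: b, X*(0), m-1 increments, m-1 death coins
    u = _chunked_uniforms(seed, n, 2 + 2 * (m - 1))
    b = omega * ndtri(u[:, 0])
    xstar = np.zeros(n) if paper_literal_init else stat_sd * ndtri(u[:, 1])
    incr = ndtri(u[:, 2 : m + 1])
    coins = u[:, m + 1 :]

    values = np.empty((n, m))
    event_time = np.full(n, horizon)
    status = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for k in range(m):
        x = mu[k] + b + xstar
        values[:, k] = np.where(alive, x, np.nan)
        if k == m - 1:
            break
        p_death = h0[k] * np.exp(beta[k] * x) * dt
        if np.any(p_death[alive] >= 1.0):
            raise StepSizeError(
                "per-step death probability reached 1; reduce dt"
            )
        dying = alive & (coins[:, k] < p_death)
        event_time[dying] = grid[k + 1]
        status[dying] = 1
        alive &= ~dying
        xstar = xstar - params.theta * xstar * dt + incr_scale * incr[:, k]
    return OUPaths(grid=grid, values=values, b=b, event_time=event_time,
                   status=status, params=params)


def simulate_ou_survival(
    config: SimConfig,
    params: OUParams,
    model: CoxTDModel,
    paper_literal_init: bool = False,
    paper_literal_step: bool = False,
    target_evaluable: Optional[tuple] = None,
) -> OUPaths:
    """Joint OU-covariate / survival paths by Euler-Maruyama.

    Per subject: b ~ N(0, omega^2); X*(0) from the stationary law
    N(0, sigma^2/(2 theta)) by default, or 0 with ``paper_literal_init``;
    each step evolves X* by -theta X* dt plus a diffusion increment
    sigma sqrt(dt) U by default (sigma U dt with ``paper_literal_step``,
    whose stationary variance vanishes with dt), then tosses a death coin
    with probability h0(t) exp(beta(t) X(t)) dt.  Paths stop at death or at
    the administrative horizon (default 10 when config.horizon is None).

    ``target_evaluable=(s, count)`` keeps simulating batches until at least
    ``count`` subjects survive to the landmark time s, mirroring designs
    that fix the number of evaluable subjects rather than n.
    """
    if target_evaluable is None:
        return _simulate_ou_batch(
            config.seed, config.n, config, params, model,
            paper_literal_init, paper_literal_step,
        )
    s, count = target_evaluable
    batches, got, batch_seed = [], 0, config.seed
    while got < count:
        batch = _simulate_ou_batch(
            batch_seed, config.n, config, params, model,
            paper_literal_init, paper_literal_step,
        )
        batches.append(batch)
        got += int(np.sum(batch.event_time >= s))
        batch_seed += 1
    return OUPaths(
        grid=batches[0].grid,
        values=np.vstack([b.values for b in batches]),
        b=np.concatenate([b.b for b in batches]),
        event_time=np.concatenate([b.event_time for b in batches]),
        status=np.concatenate([b.status for b in batches]),
        params=params,
    )


def mc_conditional_expectation(
    paths: OUPaths,
    model: CoxTDModel,
    s: float,
    x_values: Sequence[float],
    t_grid: Sequence[float],
    dX: float = 0.1,
) -> pd.DataFrame:
    """Monte Carlo estimate of E[e^{beta(t) X(t)} | T >= t, X(s) = x].

    Conditioning on X(s) = x is realised by the window |X(s) - x| < dX among
    subjects alive at s; for each t the estimate is the average of
    e^{beta(t) X(t)} over the further subset observed alive at t, i.e. with
    T strictly beyond t for deaths (a death recorded at grid time t occurred
    within the step ending at t, so X(t) is unobserved) and administrative
    censoring at the horizon counting as surviving.  Returns a frame with
    columns x_s, t, estimate, log_estimate, se, se_log, n_at_risk and an
    ``n_evaluable`` attribute (subjects alive at s).
    """
    xs = paths.value_at(s)
    evaluable = np.isfinite(xs)
    n_evaluable = int(np.sum(evaluable))
    rows = []
    for x in x_values:
        in_window = evaluable & (np.abs(xs - x) < dX)
        if not np.any(in_window):
            raise InsufficientPathsError(
                f"no paths with |X({s}) - {x}| < {dX} alive at s={s}"
            )
        for t in t_grid:
            sel = in_window & np.isfinite(paths.value_at(t))
            k = int(np.sum(sel))
            if k == 0:
                raise InsufficientPathsError(
                    f"no paths alive at t={t} in the window around x={x}"
                )
            bt = float(np.asarray(model.beta(t)))
            vals = np.exp(bt * paths.value_at(t)[sel])
            est = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(k)) if k > 1 else np.nan
            rows.append(
                {
                    "x_s": x,
                    "t": t,
                    "estimate": est,
                    "log_estimate": np.log(est),
                    "se": se,
                    "se_log": se / est if k > 1 else np.nan,
                    "n_at_risk": k,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_evaluable"] = n_evaluable
    return out


def subjects_to_csv(subjects: pd.DataFrame, path) -> None:
    """Write the subject frame (id, response_time, event_time, status,
    censor_applied); response_time empty when absent."""
    cols = ["id", "response_time", "event_time", "status", "censor_applied"]
    subjects[cols].to_csv(path, index=False)


def paths_to_csv(paths: OUPaths, path_values, path_events) -> None:
    """Write OU paths in long format (id, time, x) and a separate events
    table (id, event_time, status)."""
    n, m = paths.values.shape
    long = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), m),
            "time": np.tile(paths.grid, n),
            "x": paths.values.ravel(),
        }
    ).dropna(subset=["x"])
    long.to_csv(path_values, index=False)
    pd.DataFrame(
        {"id": np.arange(n), "event_time": paths.event_time, "status": paths.status}
    ).to_csv(path_events, index=False)
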