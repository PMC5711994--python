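"""Counting-process Cox regression engine.

Fits the Cox partial likelihood on (start, stop, event] records with left
truncation, Efron or Breslow tie handling, Newton-Raphson with step-halving,
Schoenfeld residuals, a Grambsch-Therneau style time-varying-coefficient
smoother, and (reverse) Kaplan-Meier estimation.

The risk set at an event time t consists of records with start < t <= stop
(left-continuous covariates, right-continuous counting process).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoxFit",
    "KaplanMeierEstimate",
    "NoEventsError",
    "SingularModelError",
    "InsufficientDataError",
    "fit_cox",
    "schoenfeld_tv_coefficient",
    "ph_score_test",
    "kaplan_meier",
    "read_counting_csv",
    "fit_report",
]

_DIVERGENCE_BOUND = 20.0


class NoEventsError(ValueError):
    """The data contain no events; the partial likelihood is flat."""


class SingularModelError(ValueError):
    """The information matrix is not invertible (e.g. a covariate without
    variation in any risk set)."""


class InsufficientDataError(ValueError):
    """Too few events for the requested smoother."""


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit."""

    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    names: list
    schoenfeld: pd.DataFrame          # event time + one residual column per covariate
    iterations: int
    final_grad_norm: float
    converged: bool
    divergent: bool = False
    _means: np.ndarray = field(default=None, repr=False)
    # per-event risk-set covariance V(t_k) of the covariates (n_events, p, p)
    event_info: np.ndarray = field(default=None, repr=False)

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def confidence_intervals(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.coef - z * self.se, self.coef + z * self.se]
        )


def _as_arrays(data, covariates, start, stop, event):
    start_a = np.asarray(data[start], dtype=float)
    stop_a = np.asarray(data[stop], dtype=float)
    event_a = np.asarray(data[event], dtype=int)
    X = np.column_stack([np.asarray(data[c], dtype=float) for c in covariates])
    if np.any(start_a >= stop_a):
        bad = int(np.nonzero(start_a >= stop_a)[0][0])
        raise ValueError(f"record {bad}: start must be < stop")
    return start_a, stop_a, event_a, X


class _PartialLikelihood:
    """Evaluates log partial likelihood, score and information for
    counting-process data with Efron/Breslow ties."""

    def __init__(self, start, stop, event, X, ties):
        self.start_sorted = np.sort(start)
        order = np.argsort(stop, kind="stable")
        self.stop_sorted = stop[order]
        self.X_by_stop = X[order]
        self.event_by_stop = event[order].astype(bool)
        self.X = X
        self.p = X.shape[1]
        self.start = start
        self.ties = ties

        ev_times = self.stop_sorted[self.event_by_stop]
        self.X_ev = self.X_by_stop[self.event_by_stop]
        # tie groups: events are sorted by time, groups contiguous
        self.t_unique, self.grp_start, self.grp_count = np.unique(
            ev_times, return_index=True, return_counts=True
        )
        self.ev_times = ev_times
        # expanded (group, k) rows for the Efron correction
        d = self.grp_count
        self.row_grp = np.repeat(np.arange(len(d)), d)
        self.row_k = np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)
        if ties == "efron":
            self.row_frac = self.row_k / np.repeat(d, d)
        elif ties == "breslow":
            self.row_frac = np.zeros(d.sum())
        else:
            raise ValueError(f"unknown ties method {ties!r}")
        # suffix-sum lookup indices: risk set {start < t <= stop} at each
        # unique event time, via sums over {stop >= t} minus {start >= t}
        self.idx_stop = np.searchsorted(self.stop_sorted, self.t_unique, "left")
        self.idx_start = np.searchsorted(self.start_sorted, self.t_unique, "left")
        self.start_order = np.argsort(start)

    def _risk_sums(self, w_by_stop, w_by_start):
        """Suffix sums over stop >= t minus start >= t at unique event times;
        w_* may have trailing dimensions."""
        cs = np.concatenate(
            [np.cumsum(w_by_stop[::-1], axis=0)[::-1],
             np.zeros((1,) + w_by_stop.shape[1:])]
        )
        ca = np.concatenate(
            [np.cumsum(w_by_start[::-1], axis=0)[::-1],
             np.zeros((1,) + w_by_start.shape[1:])]
        )
        return cs[self.idx_stop] - ca[self.idx_start]

    def evaluate(self, beta, want_xbar=False):
        p = self.p
        eta_by_stop = self.X_by_stop @ beta
        w_by_stop = np.exp(eta_by_stop)
        wx_by_stop = w_by_stop[:, None] * self.X_by_stop
        wxx_by_stop = wx_by_stop[:, :, None] * self.X_by_stop[:, None, :]
        # same weights ordered by start for the truncation correction
        w_sorted_start = np.exp(self.X[self.start_order] @ beta)
        X_by_start = self.X[self.start_order]
        wx_by_start = w_sorted_start[:, None] * X_by_start
        wxx_by_start = wx_by_start[:, :, None] * X_by_start[:, None, :]

        R0 = self._risk_sums(w_by_stop, w_sorted_start)
        R1 = self._risk_sums(wx_by_stop, wx_by_start)
        R2 = self._risk_sums(wxx_by_stop, wxx_by_start)

        # per-tie-group sums over the tied events themselves
        w_ev = w_by_stop[self.event_by_stop]
        wx_ev = wx_by_stop[self.event_by_stop]
        wxx_ev = wxx_by_stop[self.event_by_stop]
        s0 = np.add.reduceat(w_ev, self.grp_start)
        s1 = np.add.reduceat(wx_ev, self.grp_start)
        s2 = np.add.reduceat(wxx_ev, self.grp_start)

        g, f = self.row_grp, self.row_frac
        D0 = R0[g] - f * s0[g]
        D1 = R1[g] - f[:, None] * s1[g]
        D2 = R2[g] - f[:, None, None] * s2[g]
        if np.any(D0 <= 0):
            raise SingularModelError("empty risk set at an event time")

        loglik = float(np.sum(eta_by_stop[self.event_by_stop]) - np.sum(np.log(D0)))
        xbar_rows = D1 / D0[:, None]
        grad = np.sum(self.X_ev, axis=0) - np.sum(xbar_rows, axis=0)
        info = np.sum(
            D2 / D0[:, None, None]
            - xbar_rows[:, :, None] * xbar_rows[:, None, :],
            axis=0,
        )
        if not want_xbar:
            return loglik, grad, info
        # per-event weighted-mean covariate and risk-set covariance: average
        # the (group, k) rows within each tie group
        v_rows = (
            D2 / D0[:, None, None]
            - xbar_rows[:, :, None] * xbar_rows[:, None, :]
        )
        xbar_grp = np.zeros((len(self.t_unique), p))
        v_grp = np.zeros((len(self.t_unique), p, p))
        np.add.at(xbar_grp, g, xbar_rows)
        np.add.at(v_grp, g, v_rows)
        xbar_grp /= self.grp_count[:, None]
        v_grp /= self.grp_count[:, None, None]
        return (
            loglik,
            grad,
            info,
            np.repeat(xbar_grp, self.grp_count, axis=0),
            np.repeat(v_grp, self.grp_count, axis=0),
        )


def fit_cox(
    data: pd.DataFrame,
    covariates: Sequence[str],
    *,
    ties: str = "efron",
    start: str = "start",
    stop: str = "stop",
    event: str = "event",
    max_iter: int = 50,
    tol: float = 1e-9,
    grad_tol: float = 1e-8,
) -> CoxFit:
    """Maximise the Cox partial likelihood on counting-process records.

    ``data`` needs columns ``start``, ``stop``, ``event`` (0/1 at stop) and
    the covariate columns; covariates are constant within a record.  Newton-
    Raphson from 0 with step-halving; convergence when the score's max
    absolute entry drops below ``grad_tol`` or the coefficient change below
    ``tol`` (the score's attainable floor is set by accumulation rounding,
    about 1e-9 on large datasets).
    """
    covariates = list(covariates)
    start_a, stop_a, event_a, X = _as_arrays(data, covariates, start, stop, event)
    n_events = int(event_a.sum())
    if n_events == 0:
        raise NoEventsError("no events in the data")
    means = X.mean(axis=0)
    pl = _PartialLikelihood(start_a, stop_a, event_a, X - means, ties)

    p = X.shape[1]
    beta = np.zeros(p)
    loglik, grad, info = pl.evaluate(beta)
    loglik_null = loglik
    divergent = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SingularModelError(
                "information matrix is singular (covariate without variation?)"
            )
        # step-halving on a likelihood decrease beyond rounding noise
        noise = 1e-10 * (1.0 + abs(loglik))
        new_beta = beta + step
        new = pl.evaluate(new_beta)
        halvings = 0
        while new[0] < loglik - noise and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = pl.evaluate(new_beta)
            halvings += 1
        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        loglik, grad, info = new
        if np.any(np.abs(beta) > _DIVERGENCE_BOUND):
            divergent = True
            warnings.warn(
                "coefficient exceeded bound 20: likely monotone likelihood",
                RuntimeWarning,
            )
            break
        if np.max(np.abs(grad)) < grad_tol or delta < tol:
            break

    loglik, grad, info, xbar, event_info = pl.evaluate(beta, want_xbar=True)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise SingularModelError("information matrix is singular at the optimum")
    se = np.sqrt(np.diag(cov))

    resid = pl.X_ev - xbar
    sch = pd.DataFrame({"time": pl.ev_times})
    for j, name in enumerate(covariates):
        sch[f"resid_{name}"] = resid[:, j]

    return CoxFit(
        coef=beta,
        se=se,
        cov=cov,
        loglik=loglik,
        loglik_null=loglik_null,
        n=len(start_a),
        n_events=n_events,
        ties=ties,
        names=covariates,
        schoenfeld=sch,
        iterations=it,
        final_grad_norm=float(np.max(np.abs(grad))),
        converged=bool(np.max(np.abs(grad)) < 1e-6 and not divergent),
        divergent=divergent,
        _means=means,
        event_info=event_info,
    )


def _tricube(u):
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


def _local_linear(t_obs, y, t_eval, fraction, precision=None):
    """Local linear regression with tricube nearest-neighbour weights,
    optionally multiplied by per-point precisions (inverse variances).

    Returns fitted values and the pointwise variance sum(l_i(t)^2 / prec_i)
    of the fit through the equivalent kernel l(t)."""
    n = len(t_obs)
    if precision is None:
        precision = np.ones(n)
    k = max(int(np.ceil(fraction * n)), 2)
    fit = np.empty(len(t_eval))
    var = np.empty(len(t_eval))
    for i, t0 in enumerate(t_eval):
        d = np.abs(t_obs - t0)
        h = max(np.partition(d, k - 1)[k - 1], 1e-12)
        w = _tricube(d / h) * precision
        sw = w.sum()
        tw = t_obs - t0
        m1 = np.sum(w * tw)
        m2 = np.sum(w * tw * tw)
        denom = sw * m2 - m1 * m1
        if denom <= 1e-300 * max(sw, 1.0):
            l = w / sw
        else:
            l = w * (m2 - m1 * tw) / denom
        fit[i] = np.sum(l * y)
        var[i] = np.sum(l * l / precision)
    return fit, var


def schoenfeld_tv_coefficient(
    fit: CoxFit,
    smoother_fraction: float = 2.0 / 3.0,
    covariate: Optional[str] = None,
    level: float = 0.95,
    scaling: str = "local",
) -> pd.DataFrame:
    """Smoothed scaled-Schoenfeld estimate of the time-varying coefficient.

    Following Grambsch-Therneau, each Schoenfeld residual r_k is scaled by
    an inverse information and offset by beta-hat, so its expectation is
    approximately the time-varying coefficient at the event time; the scaled
    residuals are then smoothed by locally weighted (local linear, tricube)
    regression over event time, with a pointwise interval propagated through
    the smoother's equivalent kernel.

    ``scaling="local"`` (default) uses the risk-set covariance V(t_k) at
    each event, beta-hat + V(t_k)^{-1} r_k, whose expectation tracks the
    time-varying coefficient even where V(t) drifts from its average; the
    smoother then weights events by precision V(t_k).  ``scaling="average"``
    uses the global n_events * I^{-1} scaling (as in cox.zph), which shrinks
    the curve toward beta-hat wherever V(t) falls below its average.

    Returns a frame (time, beta_t, lo, hi).
    """
    if fit.n_events < 10:
        raise InsufficientDataError("need at least 10 events to smooth")
    if not fit.converged and not fit.divergent:
        warnings.warn("smoothing residuals of a non-converged fit", RuntimeWarning)
    if scaling not in ("local", "average"):
        raise ValueError("scaling must be 'local' or 'average'")
    j = 0 if covariate is None else fit.names.index(covariate)
    resid = fit.schoenfeld[[f"resid_{nm}" for nm in fit.names]].to_numpy()
    t = fit.schoenfeld["time"].to_numpy()

    if scaling == "average":
        scaled = fit.coef[None, :] + fit.n_events * (resid @ fit.cov.T)
        y = scaled[:, j]
        prec = None
        var_r = fit.n_events * fit.cov[j, j]
        beta_t, var_l2 = _local_linear(t, y, t, smoother_fraction)
        var_fit = var_l2 * var_r
    else:
        V = fit.event_info
        # ridge keeps near-degenerate late-time risk sets finite; their
        # precision weight is tiny so they barely influence the fit
        ridge = 1e-8 * max(float(np.max(np.trace(V, axis1=1, axis2=2))), 1.0)
        Vr = V + ridge * np.eye(V.shape[1])[None, :, :]
        scaled = fit.coef[None, :] + np.linalg.solve(Vr, resid[:, :, None])[:, :, 0]
        y = scaled[:, j]
        prec = 1.0 / np.linalg.inv(Vr)[:, j, j]  # 1 / var of scaled residual
        beta_t, var_fit = _local_linear(t, y, t, smoother_fraction, precision=prec)

    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var_fit)
    return pd.DataFrame(
        {"time": t, "beta_t": beta_t, "lo": beta_t - half, "hi": beta_t + half}
    )


def ph_score_test(fit: CoxFit, covariate: Optional[str] = None):
    """Score test for proportional hazards against a linear-in-time trend of
    the coefficient (identity time transform), one covariate at a time.
    Returns (chi2, p_value) with 1 degree of freedom."""
    from scipy.stats import chi2

    j = 0 if covariate is None else fit.names.index(covariate)
    r = fit.schoenfeld[f"resid_{fit.names[j]}"].to_numpy()
    g = fit.schoenfeld["time"].to_numpy()
    gc = g - g.mean()
    num = float(np.sum(gc * r)) ** 2
    vbar = 1.0 / (fit.n_events * fit.cov[j, j])  # average information, 1-d
    den = float(np.sum(gc * gc)) * vbar
    stat = num / den
    return stat, float(chi2.sf(stat, 1))


@dataclass
class KaplanMeierEstimate:
    """Product-limit estimate: right-continuous step function dropping at
    each distinct event time, with Greenwood variance."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n: int
    reverse: bool = False

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no drops observed
            s = np.ones_like(t)
            return float(s) if s.ndim == 0 else s
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(s) if s.ndim == 0 else s

    @property
    def median(self) -> Optional[float]:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None


def kaplan_meier(times, statuses, reverse: bool = False) -> KaplanMeierEstimate:
    """Kaplan-Meier estimator; ``reverse=True`` swaps event and censoring
    roles to estimate the censoring distribution (its median summarises
    follow-up duration)."""
    times = np.asarray(times, dtype=float)
    statuses = np.asarray(statuses, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    ev = (1 - statuses) if reverse else statuses
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = ev[order]
    tu, first = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, first)
    n_risk = times.size - first
    keep = d > 0
    tu, d, n_risk = tu[keep], d[keep], n_risk[keep]
    surv = np.cumprod(1.0 - d / n_risk)
    # Greenwood; undefined (nan) once the curve reaches 0
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(d / (n_risk * (n_risk - d)))
        variance = surv**2 * gw
    return KaplanMeierEstimate(
        times=tu, survival=surv, variance=variance, n=times.size, reverse=reverse
    )


def read_counting_csv(path, covariates: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a counting-process CSV (id, start, stop, event, x1..xp) and
    validate the record invariants, reporting offending row numbers."""
    df = pd.read_csv(path)
    required = {"id", "start", "stop", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = df.index[df["start"] >= df["stop"]]
    if len(bad):
        raise ValueError(f"start >= stop at rows {list(bad[:10])}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])]
        raise ValueError(f"event not in {{0,1}} at rows {list(bad[:10])}")
    for sid, grp in df.sort_values("start").groupby("id"):
        if (grp["start"].to_numpy()[1:] < grp["stop"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals for id {sid}")
    if covariates:
        missing = set(covariates) - set(df.columns)
        if missing:
            raise ValueError(f"missing covariate columns: {sorted(missing)}")
    return df


def fit_report(fit: CoxFit) -> dict:
    """JSON-serialisable summary of a fit."""
    ci = fit.confidence_intervals()
    return {
        "coef": {nm: float(c) for nm, c in zip(fit.names, fit.coef)},
        "se": {nm: float(s) for nm, s in zip(fit.names, fit.se)},
        "hazard_ratio": {nm: float(np.exp(c)) for nm, c in zip(fit.names, fit.coef)},
        "ci95": {nm: [float(np.exp(lo)), float(np.exp(hi))]
                 for nm, (lo, hi) in zip(fit.names, ci)},
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "n": fit.n,
        "n_events": fit.n_events,
        "ties": fit.ties,
        "convergence": {
            "iterations": fit.iterations,
            "final_grad_norm": fit.final_grad_norm,
            "converged": fit.converged,
            "divergent": fit.divergent,
        },
    }


def save_fit_report(fit: CoxFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_report(fit), fh, indent=2)
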