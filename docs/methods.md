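# Methods

## The problem

A time-dependent Cox model assumes the hazard at time t depends on the
current value of a time-dependent covariate X(t),

    h(t | X̄(t)) = h0(t) exp(β(t) X(t)).

A landmark analysis at time s instead freezes the covariate at X(s) and fits
a proportional-hazards model among the subjects still at risk at s.  Because
X can keep changing after s, the two groups defined by X(s) mix over time
and the landmark coefficient is attenuated toward 0 relative to β.  This
package computes the attenuation exactly for dichotomous covariates,
approximately for continuous Gaussian covariates, and verifies both against
matched simulations fitted with its own Cox engine.

The starting identity is that the landmark hazard equals
h0(t) · E[exp(β(t) X(t)) | T ≥ t, X(s)], valid when, conditional on being
alive at t and on X(t), survival is independent of X(s).

## Dichotomous covariates (`landcox.msm_theory`)

X(t) ∈ {0, 1} is the state of an illness-death multi-state model: 0 (no
response), 1 (response), 2 (death, absorbing), with transition hazards
λ01, λ10 (0 in the irreversible case), λ02 = h0 and λ12 = h0·e^β.  The
conditional-independence requirement above is satisfied when the multi-state
process is Markov, which is assumed throughout.

Transition probabilities P_gh(s, t) solve the Kolmogorov forward equations
dP(s, u)/du = P(s, u) Q(u), integrated with an adaptive high-order
Runge–Kutta scheme (DOP853, atol 1e−10 / rtol 1e−8; probabilities close to 0
or 1 control a log-ratio output, hence the tight tolerances).  Conditional
prevalences among survivors are π_g1(s, t) = P_g1 / (P_g0 + P_g1).  The
time-varying landmark coefficient is

    exp(β_LM(t|s)) = (π_10 + e^β(t) π_11) / (π_00 + e^β(t) π_01),

which in the irreversible case reduces to
β(t) − log(1 + (e^β(t) − 1) π_01(s, t)); it always lies between −β(t) and
β(t), and its derivative in t at t = s is
β′(s) − (e^β(s) − 1){λ01(s) + λ10(s) e^{−β(s)}} (β′ by central difference,
step 1e−5·max(1, s)).

**What a proportional-hazards landmark fit estimates.**  Fitting a constant
coefficient to a time-varying truth yields approximately the weighted time
average

    β*_LM(s) ≈ ∫ β_LM(t|s) w(t) dt / ∫ w(t) dt,
    w(t) = var(X | T = t) · h(t) S(t) C(t),

with h, S the hazard and survival of the landmark population (mixture over
X(s) with shares from state occupation since time 0) and C the censoring
survival function.  Two genuinely open choices here:

* *Which covariate's variance.*  The misspecified model's covariate is the
  frozen X(s), so the default takes var(X(s) | failure at t); the variance of
  the current state X(t) is available via `covariate="current"`.  Under the
  reference conditions (λ01 = 0.2, λ = 0.1, β = 1, s = 2) the default gives
  0.511 and the current-covariate variant 0.534, against a simulated mean of
  0.503 — the default is kept.
* *Approximation quality.*  The weighted average is a first-order
  approximation.  The package also solves the *exact* population score
  equation of the misspecified fit (`landmark_ph_limit`), which matches the
  simulation means to well within Monte Carlo error at every panel and
  landmark checked (e.g. 0.5019 vs 0.5029 ± 0.0020 at s = 2); the weighted
  average sits about 0.01 above it at those conditions.  Tests that close the
  theory–simulation loop at 3-MC-SE precision therefore exist in two forms:
  against the weighted average (which can exceed that precision by its own
  approximation error, and then fails honestly) and against the exact limit
  (which passes).

Quadrature is trapezoidal on a uniform 2000-point grid (the integrands are
smooth); the default horizon is the 99.9th percentile of the event-time
distribution, capped by the censoring support.  The study design's censoring
survival C(t) = 1 for t < 7.5, (12.5 − t)/5 on [7.5, 12.5], 0 afterwards is
provided as `uniform_censoring_survival(7.5, 12.5)`.

## Continuous covariates (`landcox.ou_theory`)

X_i(t) = μ(t) + b_i + X*_i(t) with b_i ~ N(0, ω²) a stable person effect and
X* a mean-zero Ornstein–Uhlenbeck diffusion dX* = −θX*dt + σdW.  The
user-facing parameters are the total variance σ²_tot = ω² + σ²/(2θ), the
intraclass correlation ρ = ω²/σ²_tot (the share of variance from the person
effect and the asymptote of the lag correlation) and the mean-reversal rate
θ; ω² and σ² are derived so the decomposition is exact.  μ(t) defaults to 0.
The lag correlation is ρ(s, t) = ρ + (1 − ρ)e^{−θ|t−s|}.

Ignoring the selection effect of survival to t, (X(s), X(t)) is bivariate
normal and the conditional expectation in the landmark hazard is a Gaussian
moment generating function:

    log E[e^{β(t)X(t)} | T ≥ t, X(s)]
      ≈ β(t){μ(t) + ρ(s,t)(X(s) − μ(s))} + ½β(t)² σ²_tot(1 − ρ(s,t)²),

whose derivative in X(s) gives the attenuation relation
β_LM(t|s) ≈ β(t)ρ(s, t): the coefficient decays exponentially from β at
t = s to the asymptote β·ρ.  These are *stated approximations*; the module
never silently corrects for survival selection.  Selection pulls the true
conditional expectation below the approximation (subjects with high X(t) die
preferentially), increasingly so for larger baseline hazard or total
variance — the Monte Carlo machinery below quantifies this.

## Simulators (`landcox.simulate`)

**Illness-death histories** are sampled *exactly* by inversion of competing
exponentials (from state 0: min(Exp(λ01), Exp(λ02)); death hazard in state 1
is λ02·e^β), so no discretisation error enters the simulation-study means.
The reversible model alternates states until death.  Uniform(lo, hi)
censoring and an administrative horizon are independent of everything else;
a response after the end of follow-up is never observed.  The uncensored
study panels use horizon 50, effectively complete follow-up for the rates
studied (marginal survival < 1%); the value is configurable because the
weighted-average coefficient depends on it in principle.

**OU paths** are evolved by Euler–Maruyama with step dt (default 0.01) to a
horizon (default 10), with death decided each step by a Bernoulli coin with
probability h0(t)e^{β(t)X(t)}dt (an error is raised if this reaches 1).  Two
deliberate deviations from a literal reading of the Monte Carlo recipe being
reproduced, both reversible by flag:

* the diffusion increment is σ·√dt·U (flag `paper_literal_step` restores
  σ·U·dt, whose stationary variance σ²dt/(2θ) collapses with dt — by
  standard SDE theory the √dt scaling is what makes the process's covariance
  match the formula above, and a test documents the mismatch);
* X*(0) is drawn from the stationary law N(0, σ²/(2θ)) (flag
  `paper_literal_init` restores X*(0) = 0, which is only asymptotically
  stationary; the curve-reproduction runner uses the literal initialisation
  to match the procedure it reproduces).

Reproducibility: generators use a counter-based Philox stream with a fixed
number of draws per subject in fixed-size subject blocks, so the first n₁
subjects are identical for any n ≥ n₁ and identical configurations give
byte-identical CSVs.  A `target_evaluable` mode keeps simulating batches
until a requested number of subjects survive the landmark, mirroring designs
that fix the evaluable count (500,000 at full scale) rather than n.

**Monte Carlo conditional expectation.**  E[e^{βX(t)} | T ≥ t, X(s) = x] is
estimated by averaging e^{βX(t)} over paths observed alive at t whose X(s)
lies within ±dX (default 0.1) of x.  A death recorded at grid time t
occurred within the step ending at t, so such paths are excluded at t.  The
window induces a small bias at t = s (order β²dX²/6 plus a density-slope
term, ~2e−3 at the reference settings) which matters only where the Monte
Carlo error is even smaller; comparisons with the MGF approximation are
therefore made beyond the landmark.

## Cox engine (`landcox.coxfit`)

A self-contained counting-process partial-likelihood engine: risk set at an
event time t is {start < t ≤ stop} (left truncation honoured), Efron
(default) or Breslow ties — continuous simulated times make ties
measure-zero, Efron is the safer default for real data.  Newton–Raphson from
0 with step-halving; risk-set sums are computed by suffix cumulative sums
over records sorted by start and by stop, so one evaluation is
O(n log n).  Convergence when the score's largest entry falls below 1e−8 or
the coefficient change below 1e−9: the score's attainable floor is set by
float64 accumulation (≈1e−9 on 2·10⁴ records), and step-halving tolerates
likelihood decreases within that rounding noise.  |β̂| exceeding 20 flags a
monotone likelihood.  Standard errors come from the inverse observed
information; covariates are centred internally for numerical stability
(the partial likelihood is location-invariant).

**Time-varying coefficient from Schoenfeld residuals.**  Each event's
residual r_k (covariate of the failing subject minus the risk-set weighted
mean) is scaled so its expectation approximates the time-varying
coefficient, then smoothed over event time by locally weighted (local
linear, tricube, nearest-neighbour span, default fraction 2/3) regression on
the raw time axis.  The default scaling uses the *local* risk-set covariance
V(t_k): β̂ + V(t_k)^{-1} r_k, with smoothing weights proportional to the
precision V(t_k).  The popular global approximation β̂ + n_e I^{-1} r_k
(`scaling="average"`) has expectation β̂ + n_e I^{-1} V(t)(β_LM(t) − β̂),
which shrinks toward β̂ wherever V(t) drifts below its average — on the
reference landmark dataset this distorts the curve by ~0.15 at late event
times, while the local scaling tracks the exact theory curve across the
central 80% of event times.  Pointwise intervals propagate the residual
variance (V(t_k)^{-1}, or n_e I^{-1} for the average scaling) through the
smoother's equivalent kernel; they are pointwise, not simultaneous.  A
1-degree-of-freedom score test against a linear-in-time coefficient trend
(identity transform) accompanies the curve and holds its nominal level
under proportional hazards.

Kaplan–Meier (with Greenwood variance) and reverse Kaplan–Meier (censoring
as the event; its median summarises follow-up) round out the engine.  The
median convention is the smallest time with survival ≤ 0.5.

## Studies (`landcox.experiments`)

A landmark dataset at s keeps subjects with follow-up strictly beyond s,
freezes the covariate at X(s) and encodes rows with entry s (left
truncation); a test verifies this is identical to resetting time to 0.  The
dichotomous study panels simulate `reps` datasets of n subjects, fit the
time-dependent Cox model on the start–stop encoding and a
proportional-hazards landmark model at each landmark, and summarise
replicate means with Monte Carlo standard errors.  Per-replicate seeds are
derived deterministically from the study seed; a failed replicate fit is
recorded and excluded, with an error if more than 1% fail.

Desk-scale defaults are 250 replicates (the printed panels used 1000) and
50,000 OU paths (`--full` restores 1000 replicates / 500,000 evaluable);
at 250 replicates the Monte Carlo SE of a panel mean is ≈0.002 (uncensored
landmarks, where most follow-up survives) up to ≈0.01–0.02 (landmark 10
under censoring, where each replicate retains few events).

The transplant waiting-list analysis expects a user-supplied CSV (columns
`futime`, `fustat`, `wait_time`, `mismatch`; days are converted to years by
365.25, month landmarks as s/12 years — the conversion is a package choice,
stated here because the source data are day-granular).  Transplanted
patients are split into mismatch score > 1.58 versus ≤ 1.58 (the score
distribution's upper quartile; fixed, not recomputed from the supplied
file), with unscored transplanted patients grouped in the low set; the
time-dependent fit uses both indicators as start–stop covariates, each
landmark fit uses the high-mismatch indicator frozen at s among patients at
risk at s.  A transplant recorded at or after the end of follow-up cannot
open a nonempty (wait, futime] interval and leaves the covariate at 0.  The
dataset is not bundled; the test suite exercises the pipeline's schema
validation and output layout on a synthetic, structure-compatible stand-in
and asserts no published coefficient values.

## What the tests do and do not show

The synthetic generators have exactly the structure the theory assumes
(Markov multi-state process; Gaussian OU covariate; independent censoring;
no measurement error, no interval sampling of the covariate).  Passing tests
therefore validate the formulas, the engine and their mutual consistency —
not robustness to misclassification, infrequent measurement, informative
censoring or non-Markov dynamics, all of which are out of scope.  Measured
agreement under those conditions: panel means within 3 Monte Carlo SE of
the published values at 250 replicates; the exact misspecification limit
within 3 MC SE of the simulated means; the weighted-average formula within
~0.01 of the exact limit (its intrinsic accuracy at these conditions).

## Known limitations

* Three states only; no interval censoring of the multi-state process; the
  Markov assumption is not checked from data.
* The MGF-based continuous-covariate theory ignores survival selection by
  construction; it degrades as h0 or σ²_tot grow.
* The Cox engine fits unstratified, unpenalised models with a small number
  of covariates; robust/frailty variance is not provided.
* The weighted-average coefficient (and its exact-limit companion) assume
  the landmark population's covariate is binary.
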