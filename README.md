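# landcox

Landmark analysis versus time-dependent Cox regression: what does a
landmark fit actually estimate when the covariate keeps changing?

## The problem

Time-dependent covariates in survival analysis — response to treatment,
transplant status, a longitudinal biomarker — are commonly analysed in one
of two ways.  A **time-dependent Cox regression** models the hazard through
the covariate's current value,

    h(t | X̄(t)) = h0(t) exp(β(t) X(t)),

fitted on counting-process (start, stop] records.  A **landmark analysis**
fixes a time s, keeps the subjects still at risk at s, and uses X(s) as a
time-fixed covariate in a proportional-hazards model from s onward.  Because
subjects with X(s) = 0 may later switch to 1 (and vice versa), the two
groups grow more alike over time and the landmark coefficient β_LM(t|s) is
*attenuated*: it starts at β(s) at the landmark and is pulled toward 0 as t
grows.

`landcox` makes this attenuation computable, for biostatisticians designing
or interpreting landmark analyses:

* **Dichotomous covariates** (`landcox.msm_theory`) — X(t) is the state of
  an illness-death multi-state model with hazards λ01, λ10, λ02 = h0,
  λ12 = h0·e^β.  Transition probabilities come from the Kolmogorov forward
  equations; the landmark coefficient is exact:

      exp(β_LM(t|s)) = (π_10 + e^β(t) π_11) / (π_00 + e^β(t) π_01),

  where π_g1(s,t) are prevalences among survivors.  The module also
  computes the weighted time-average β*_LM(s) that a (misspecified)
  proportional-hazards landmark fit approximately estimates, and the exact
  large-sample limit of that fit.
* **Continuous Gaussian covariates** (`landcox.ou_theory`) — X(t) is an
  Ornstein–Uhlenbeck process plus a random person intercept, with lag
  correlation ρ(s,t) = ρ + (1−ρ)e^{−θ|t−s|}; ignoring survival selection,
  β_LM(t|s) ≈ β(t)·ρ(s,t).
* **Simulators** (`landcox.simulate`) — exact illness-death sampling,
  Euler–Maruyama OU paths with Bernoulli-coin deaths, and the Monte Carlo
  conditional-expectation estimator that quantifies the survival-selection
  effect the Gaussian approximation ignores.
* **A self-contained Cox engine** (`landcox.coxfit`) — counting-process
  partial likelihood with left truncation, Efron/Breslow ties, Schoenfeld
  residuals, a smoothed time-varying-coefficient estimator with pointwise
  intervals, and (reverse) Kaplan–Meier.
* **Study runners** (`landcox.experiments`) — landmark-dataset
  construction, the full simulation studies, theory-vs-Monte-Carlo curves,
  and a heart-transplant waiting-list analysis for a user-supplied CSV.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

## Worked example

Reference setting: exponential response rate λ01 = 0.2, death rate
λ = 0.1 without response, log hazard ratio β = 1, landmark at s = 2.

```python
from landcox import (CoxTDModel, IllnessDeathRates, SimConfig, BetaStarInputs,
                     beta_star, landmark_coef_irreversible, prevalence,
                     simulate_illness_death, build_landmark_dataset,
                     counting_process_encoding, fit_cox)

model = CoxTDModel.from_constants(0.1, 1.0)
rates = IllnessDeathRates.from_cox_model(model, 0.2)
print("pi01(2,4)    =", round(prevalence(rates, 2.0, 4.0).pi01, 4))
print("beta_LM(4|2) =", round(landmark_coef_irreversible(model, rates, 2.0, 4.0), 4))
print("beta*_LM(2)  =", round(beta_star(model, rates, BetaStarInputs(s=2.0, t_hor=50.0)), 4))

subjects = simulate_illness_death(SimConfig(n=10_000, seed=1, horizon=50.0),
                                  lambda01=0.2, lambda02=0.1, beta=1.0)
td = fit_cox(counting_process_encoding(subjects), ["x"])
lm = fit_cox(build_landmark_dataset(subjects, 2.0).rows, ["x"])
print(f"TD Cox fit     = {td.coef[0]:.3f} (SE {td.se[0]:.3f})")
print(f"landmark s=2   = {lm.coef[0]:.3f} (SE {lm.se[0]:.3f})")
```

prints

```
pi01(2,4)    = 0.2915
beta_LM(4|2) = 0.5939
beta*_LM(2)  = 0.5107
TD Cox fit     = 1.012 (SE 0.024)
landmark s=2   = 0.475 (SE 0.025)
```

Reading this: two time units past the landmark, 29% of the survivors who
were response-free at s = 2 have since responded, which attenuates the
landmark coefficient from 1 at t = s to 0.59 at t = 4.  A
proportional-hazards landmark fit averages this decaying curve with weights
var(X(s)|T=t)·h(t)S(t)C(t), predicting an estimate near 0.51 — and on one
simulated dataset of 10,000 subjects the time-dependent Cox fit recovers
the generating β = 1 while the landmark fit at s = 2 returns 0.48: the same
covariate, analysed two standard ways, gives a coefficient either at the
truth or attenuated by half, exactly as the theory predicts.

## Command line

```sh
landcox simulate illness-death --n 10000 --lambda01 0.2 --lambda02 0.1 \
    --beta 1 --censoring uniform:7.5:12.5 --seed 1 --out subjects.csv
landcox fit --data counting.csv --covariates x --ties efron
landcox tvcoef --data counting.csv --covariates x --fraction 0.6667 --out curve.csv
landcox experiment fig2|fig3|fig4|fig5|fig6 [--full] [--seed 1]
landcox experiment stanford --data heart.csv
```

`landcox experiment stanford` expects a CSV of the classic heart-transplant
waiting-list cohort with columns `futime` (days to death/censoring),
`fustat` (1 = died), `wait_time` (days to transplant, empty if none) and
`mismatch` (donor–recipient mismatch score); the dataset is not bundled.

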