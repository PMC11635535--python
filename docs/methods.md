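# Methods

## Data-generating model

The simulator produces one virtual domain at a time: a two-arm comparison of
an intervention against contemporaneous placebo inside a CKD platform trial.

**Accrual.** Enrollment times follow a homogeneous Poisson process at
`accrual_rate` participants/week (default 9.6), truncated at
`max_per_arm × (n_arms + 1)` participants (default 1000). The default rate
is chosen so a domain accrues roughly 750 participants by month 18 and
reaches its cap shortly after month 24, matching the enrollment milestones
of the worked interim example the package replays.

**Baseline covariates.** Baseline eGFR is normal with mean 52.9 and SD 29.3
mL/min/1.73 m², truncated at the eligibility floor of 25 — the truncation
means every simulated participant passes the core screen, and the realized
mean sits near 57. ln(UACR) is normal with median 89 mg/g and
σ = (ln 420 − ln 20)/(2 × 0.6745) ≈ 2.26, reproducing the registry's
interquartile range of 20–420 mg/g. Age and sex are drawn to match the same
registry (mean 64.5 y, 58.7% female) and only matter when exporting
creatinine-style datasets.

**eGFR trajectories.** For participant *i* at scheduled week *w*,

    eGFR_i(w) = b_i + A · onset(w) + (s_i + C) · w/52.18 + ε_iw

with b_i the baseline, s_i ~ N(−3.42, 5.5²) the latent placebo slope
(per year), A the acute treatment shift, C the chronic slope effect, and
ε_iw ~ N(0, 4.5²) independent visit noise. `onset(w)` rises linearly from 0
to 1 over weeks 0–4 (the hemodynamic window) and, when the acute effect is
reversible (the default), falls back to 0 linearly across the 4-week
washout, so the week-108 value carries no acute component. One constant,
52.18 weeks/year, is used for every week→year conversion. Trajectories are
floored at 0.1 mL/min/1.73 m² since eGFR cannot be negative; the floor binds
only for extreme decliners and slightly attenuates estimated contrasts in
heavy-progression scenarios.

The default placebo slope is the albuminuric (UACR > 300 mg/g) registry
subgroup rate of −3.42/yr rather than the overall −1.67/yr, because the
trial targets progressive CKD; both are plain parameters.

**Variance components.** No registry or protocol source states the
between-participant slope SD or the residual SD. The defaults (5.5 and
4.5) were chosen so the slope-contrast standard error at 500/arm on the
default visit schedule is ≈ 0.38 mL/min/1.73 m² per year, which makes the
design's stated 90% power at a 1.3/yr effect internally consistent as a
single-test calculation (Φ(1.3/0.38 − z₀.₉₈₅) ≈ 0.89). Both are
configurable, and simulated operating characteristics should always be read
relative to this documented choice.

**UACR trajectories.** ln UACR_i(w) = baseline_i + U·1[w ≥ 24] + η_iw with
η ~ N(0, 0.9²); the treatment log-ratio U is constant from the 6-month
assessment onward (the design only uses the week-24 contrast) and is not
reversed during washout.

**Dropout.** Independent exponential with hazard −ln(1 − r) per year for an
annual rate r, so retention after t years is exactly (1 − r)^t; with the
default r = 0.05, 90.3% of participants retain the week-104 visit.
Kidney-failure-driven (informative) censoring is not modeled.

**What the generator does not emulate.** Real trials have site effects,
measurement batch effects, visit-window jitter, informative dropout,
nonlinear trajectories near kidney failure, and UACR effects that develop
gradually; passing tests therefore demonstrate the decision machinery and
its calibration under the stated model, not robustness to those features.

## Inference

All decisions act on flat-prior normal posteriors N(estimate, SE²).

**Chronic slope.** The reference backend is a linear mixed model for
repeated measures — random intercept and slope per participant, fixed
arm, time, and arm×time effects — fit by REML (statsmodels MixedLM),
restricted to visits in the chronic window (week 4 to 104, or 4 to 52 while
follow-up is immature). The arm×time coefficient and its standard error are
the posterior. The arm main effect absorbs the constant acute shift inside
the window, so the slope contrast is unbiased in the presence of a
hemodynamic effect.

A precision-weighted two-stage estimator serves as the analytic backend for
Monte-Carlo work and as the fallback when the mixed model fails to
converge: per-participant OLS slopes b_i with within-participant variance
σ̂²/Sxx_i (σ̂² pooled over stage-1 residuals) are combined with weights
1/(σ̂²/Sxx_i + τ̂²), τ̂² a method-of-moments estimate of the
between-participant slope variance. On balanced complete data the weights
are equal and the contrast coincides with the mixed-model contrast exactly
(tested to 1e-6); under staggered entry and dropout the weights downweight
short, noisy slopes. Monte-Carlo runs (`run_trial`, `estimate_oc`) default
to this backend purely for speed — a 500-replicate operating-characteristic
run fits tens of thousands of interim models.

**UACR.** The week-24 endpoint is the between-arm contrast of the change in
ln(UACR) from baseline to the scheduled visit nearest week 24 (within ±4
weeks; week 26 on the default schedule), with variance from the per-arm
sample variances. A change-score contrast was preferred over
baseline-adjusted ANCOVA for transparency; the baseline-adjusted option can
be layered on without changing the decision contract. `1 − exp(mean)` maps
the log ratio to a percent reduction.

**Washout change.** The contrast of eGFR(108) − eGFR(0). For a fully
reversible acute effect and no noise, this change annualized equals the
chronic slope contrast — the equivalence that justifies using on-treatment
chronic change at immature interims; it is enforced as a generator
invariant test.

**Posterior reconstruction.** A published summary (point, 95% CI) defines a
normal posterior with σ = width/(2 × 1.959964). For UACR the percent scale
is first mapped to log ratios (β = ln(1 − r/100); note the upper percent
limit maps to the lower log limit). All ten probabilities printed in the
worked four-interim example are reproduced within ±0.01 — the residual
discrepancy is CI rounding — which is the evidence that the published
posteriors are effectively normal and that the flat-prior normal
approximation is an adequate reference backend (an MCMC backend can be
plugged in behind the same `PosteriorSummary` contract).

## Decision engine

Gates are completer counts: a participant completes week *w* when their
week-*w* visit survived dropout and `enroll_week + w ≤ calendar_week`; a
gate opens when every compared arm has at least `completers_gate` (default
100) such participants. Reviews run every 26 weeks starting at the first
multiple at which the earliest (24-week) gate could possibly hold given
enrollment. At each review: success is evaluated first (so a treatment
crossing both thresholds stops for success), then the UACR and slope
futility rules, either of which alone can stop the domain; otherwise the
domain continues. The slope endpoint switches from the week 4–52 window to
the full 4–104 window once 100/arm complete week 104, mirroring the
increasing precision across published interim panels. On any stop the
domain closes; otherwise a final analysis runs when the last enrollee
reaches week 108.

Futility gates stay active at every review, including after success
eligibility — both defaults documented as open design choices.

## Operating characteristics and calibration

`estimate_oc` aggregates decision rates (with binomial Monte-Carlo standard
errors), mean sample size, and mean decision week over independently seeded
replicates; seeds derive from one master seed through `SeedSequence.spawn`,
so every run is bit-reproducible and adding replicates never perturbs
earlier ones.

`calibrate_threshold` simulates null trials once with the success threshold
pinned at 1, records each trial's maximum success-eligible posterior
probability, and scans a 0.001-step grid — common random numbers across the
grid make the estimated error rate monotone in the threshold. Calibration
runs with futility gates off by default: futility stopping can only lower
the realized null success rate, so the threshold calibrated against
repeated success testing alone is conservative for the full design (with
futility on, most null trials never reach a success look at all and the
"calibrated" threshold would collapse below the single-look value for the
wrong reason). With a single look the calibrated threshold lands at ≈ 0.975
(a one-look posterior rule P(δ > 0) > c is a z-test at Φ⁻¹(c)); repeated
looks push it upward, consistent with the design's 0.985.

Simulation sizes used in the shipped tests and acceptance script — 500
replicates for error/power estimates, 200 for coverage, 60–150 for
directional checks — were chosen as the smallest sizes at which the
binomial Monte-Carlo error is comfortably inside each assertion band.

## Numerical choices and degenerate inputs

- Convergence failures or singular fits of the mixed model fall back to the
  two-stage estimator with a warning; the two-stage path needs at least two
  participants per arm with two or more window visits, otherwise a gated
  error tells the decision engine the endpoint is not analyzable.
- Noise-free cohorts give zero estimated variance; posterior SDs are floored
  at 1e-12 to keep the normal-posterior contract valid.
- Completer counts and gate flags are monotone in calendar time by
  construction; interim decisions are pure functions of (data cut, config).
- Configuration objects validate their invariants at construction, and the
  config-file loader rejects unknown keys outright.

## Known limitations

- Operating characteristics inherit every generator simplification listed
  above; in particular, power statements depend on the documented variance
  defaults. Under those defaults the full adaptive design delivers ≈ 0.83
  power at a 1.3/yr effect — below the idealized 0.89 single-test value,
  the difference going to surrogate-futility leakage (an effective drug can
  still lose a futility coin-flip at an early look) and dropout.
- The per-domain analysis is marginal; platform-level family-wise error
  across domains is out of scope, as are response-adaptive randomization,
  rescue randomization, and time-to-event (proportional hazards) analyses
  of the clinical events the package derives.
- Multi-domain simulation assumes additive effects with no interaction.
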