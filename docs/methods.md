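# Methods

`melscure` implements a Bayesian joint model for a longitudinal biomarker and
an interval-censored time-to-event outcome with a cured subpopulation,
motivated by first-trimester pregnancy monitoring: serial log10 beta-HCG
measurements and the time of early fetal loss, which is never observed
exactly and never occurs for most women.

## Model

**Longitudinal submodel.** For woman *i* at time *t* (days), the log10
hormone level is

    y_i(t) = mu_i(t) + eps_i(t),      eps_i(t) ~ N(0, sigma_i^2),
    mu_i(t) = a_i1 / (1 + exp{-(t - a_i2)/a_i3}),   a_ik = exp(theta_k + b_ik),

a three-parameter logistic growth curve: `a_i1` is the plateau, `a_i2` the
inflection day, `a_i3` the rise time-scale. The *mixed-effects
location-scale* (MELS) variant gives every woman her own residual SD,
`sigma_i = exp(theta4 + b_i4)` (or `exp(theta4)` when she has a single
measurement, where `b_i4` cannot be informed); the *reference* variant uses
one global `sigma`. Random effects `b_i` are MVN(0, Sigma) with Sigma 3x3
(reference) or 4x4 (MELS).

**Survival submodel.** A woman is cured (never miscarries) with probability
`eta = logistic(nu)`. A susceptible woman faces the proportional hazard

    h_i(t) = phi t^{phi-1} exp{lam + alpha1 mu_i(t) + alpha2 sigma_i^2},

a Weibull baseline modulated by the current longitudinal mean (association
`alpha1`) and, in the MELS variant, the woman's error variance
(association `alpha2`). The reference variant is the `alpha2 = 0` special
case of the same code path. Because `mu_i(t)` varies in time, the cumulative
hazard `H(t)` has no closed form; it is evaluated by fixed-order
Gauss-Legendre quadrature (order 20 by default — order 15 leaves worst-case
relative errors slightly above 1e-6 against an adaptive oracle; order 20
achieves ~4e-8; configurable).

**Likelihood.** Subjects factorize: longitudinal Gaussian terms for every
visit; `(1-eta)[S(t_L) - S(t_R)]` for a woman whose event is detected in
`(t_L, t_R]`; `eta + (1-eta) S(t_c)` for a woman event-free at `t_c`.
Interval probabilities are floored at 1e-300 before the log to survive
sampler warm-up; the flooring is never active in converged fits.

**Priors.** Normal(0, 10^2) on all fixed effects (theta's, nu, lam,
alpha's); half-Cauchy(0,1) on the Weibull shape `phi` and — reference
variant — on the error *variance* `sigma^2` (the literal reading of the
source prior specification); inverse-Wishart on Sigma. The published
inverse-Wishart hyperparameters (5x5 identity scale, 4 df) are dimensionally
inconsistent with a 3- or 4-dimensional Sigma and improper; we use an
identity scale of the model's own dimension with df = dim + 2, the weakly
informative proper choice, configurable through `FitConfig.iw_df`.

## Posterior computation

No probabilistic-programming backend is available in this environment, so
the sampler is implemented here directly:

* **NUTS** (multinomial variant with biased progressive sampling, max tree
  depth 10, divergence threshold 1000) over all global parameters and
  standardized random effects, with analytic gradients of the full joint
  log posterior. Step size is tuned by dual averaging (target acceptance
  0.8) and a diagonal mass matrix by Welford estimation over expanding
  warm-up windows, mirroring the standard dynamic-HMC warm-up schedule.
* **Conjugate Gibbs** refresh of Sigma given the centered random effects:
  Sigma | b ~ inverse-Wishart(I + sum b_i b_i', df0 + N). The NUTS update
  uses the non-centered parameterization `b_i = chol(Sigma) z_i` with the
  factor held fixed; after each Gibbs draw the `z` block is re-standardized
  so `b` is unchanged (interweaving).

Three reparameterizations matter for geometry: `phi` is sampled as
`log(phi)`; the reference `sigma` as `log(sigma)`; and the Weibull log-scale
is sampled as `lamt = lam + phi log(t0) + alpha1 mu_bar` with data-derived
constants `t0` (mean survival time) and `mu_bar` (mean response). The last
removes an extreme `lam`-`phi`-`alpha1` posterior ridge (natural-scale `lam`
must shift by ~`log(t0)` per unit of `phi` to keep the hazard level fixed);
draws are reported on the natural scale.

Chains are initialized from data moments (plateau from the y upper quantile,
inflection from the median visit time, cure logit from the censoring split,
Weibull shape from the inverse coefficient of variation of the detection
midpoints, unit cumulative hazard at `t0`), with per-chain jitter. A vague
random initialization places `lam` ~15 units from its posterior inside a
floored-likelihood plateau and reliably stalls.

The likelihood/gradient inner loop is numba-compiled; a pure-numpy
reference implementation is kept and the two are asserted identical in the
test suite. Gradients are verified against finite differences.

Defaults follow the published protocol: 3 chains, 6000 iterations, first
half discarded. Convergence is summarized by rank-normalized split-Rhat and
bulk ESS (arviz estimators); fits warn at Rhat > 1.01.

## Synthetic cohorts: the stated world

`simulate_dataset` emulates the structure of the motivating Chilean cohort
(173 women, 1-6 irregular visits each, 10-day detection intervals, a
majority never miscarrying). Stated conditions:

* scenario truths exactly as published (Scenario I: theta = (1.5, 2.7, 1.9),
  sigma = 0.25, lam = -14.5, phi = 4, alpha1 = -0.6,
  Sigma = diag(0.02, 0.08, 0.17); Scenario II: theta4 = -2, lam = -14.7,
  phi = 3.9, alpha1 = -0.4, alpha2 = 3.1, Sigma = diag(0.02, 0.07, 0.1, 0.6));
* N = 200 women, 1-4 or 5-10 visits each, uniform on (10, 80) days
  (the source never states the visit process; Figs. of the cohort show
  measurements within ~80 days);
* cure fraction 0.7 (not stated in the source; matches the cohort's
  124/173 normal pregnancies);
* event times by inversion of the quadrature cumulative hazard at
  Exponential(1) deviates (bracketed root-finding, |H(T)-E| < 1e-8).

**Observation scheme.** The scheme is *exogenous given the visit schedule*,
which makes the fitted likelihood exactly the probability of the
observables — this took several design corrections whose necessity we
established empirically (see "Design corrections" below):

* every woman keeps her full visit schedule by default (the model treats
  the biomarker as independent of the event time given the random effects,
  so post-event measurements are within-model); an optional realism mode
  (`truncate_visits=True`) discards visits at or after the event and is a
  documented, deliberate misspecification;
* a detected event is recorded as the cell of an inspection partition
  containing the true time: consecutive 10-day detection windows anchored
  at the last visit before the event, truncated at the next scheduled
  visit and at the study end;
* follow-up ends administratively at day 150 (default): any early loss is
  detected by then (detection continues past the last scheduled visit,
  reflecting symptom-driven clinical follow-up), and every woman without a
  detected event — cured or not — is right-censored at the study end.

Under Scenario truths this yields ~28-29% interval-censored women, matching
the cohort's 49/173.

**Design corrections.** Three superficially natural choices make the
generator inconsistent with the likelihood, and each was diagnosed by an
importance-sampled marginal-likelihood comparison (truth must beat any fixed
alternative on average; when it loses, the generator is wrong):

1. *Extending the recorded interval from the last visit to the detection
   time* ((t_L, t_L + k w]) implies the event lies in the final w-day
   sub-window while the likelihood spreads it over the whole interval;
   recording the partition *cell* fixes this.
2. *Right-censoring only cured women* (always detecting susceptible events)
   contradicts the mixture factor `eta + (1-eta)S(t)`, which expects
   susceptible survivors among the censored; with it, a spurious
   "no-cure, flattened-Weibull" mode beats the truth by ~10 nats and flips
   the sign of alpha1.
3. *Ending detection at the last visit* (mean day ~55 with 1-4 visits)
   leaves S(t_cens) so large that a no-cure Weibull mimics the cure mixture
   within half a nat at N = 200; the cure fraction is then decided by prior
   volume (40% of the Normal(0,100) nu-prior lies on the eta~0 shelf) and
   the posterior collapses to no cure. Administrative censoring at day 150,
   where S ~ 1e-3 at truth, identifies the mixture.
4. *Truncating visits at the event* interacts with the n_i = 1 scale rule:
   women who die right after their first visit are disproportionately the
   high-sigma^2 women (alpha2 sigma_i^2 drives early events), yet with one
   retained visit the likelihood scores them with exp(theta4) and ignores
   b4 — measured at N = 100, this alone biases alpha2 by ~-4.6 and masks
   the variance-sharing signal. Keeping the full schedule removes it.

What a green simulation test does **not** establish: behavior under the
real cohort's informative visiting (hormone measured only until death — the
real-data likelihood shares this limitation), under misspecified trajectory
shapes, or under visit processes correlated with the biomarker.

The generator always uses the *scheduled* visit count for the noise SD and
the hazard. In the default (full-schedule) mode this equals the observed
count and the fitted likelihood is exact. In the truncation mode the MELS
scale rule becomes circular (sigma_i depends on the visit count, which
depends on the event time, which depends on sigma_i through the hazard) and
women scheduled for >= 2 visits but retaining one are scored with
`exp(theta4)` instead of their true `exp(theta4 + b4)` — part of why that
mode is labelled a misspecification study, not a recovery setting.

## Simulation study

`run_study` repeats simulate -> fit -> summarize, reporting per-parameter
bias (mean posterior mean minus truth) and 95% coverage probability with
binomial Monte-Carlo SEs. Replicates whose monitored parameters exceed
split-Rhat 1.1 are excluded and counted (silent inclusion would corrupt the
bias estimates; the threshold and the point estimator — posterior mean —
are package choices, the source names neither). The full published protocol
(R = 1000, N = 200, 6000 iterations) is available as `FULL_PROTOCOL`; the
default reduced protocol (R = 50, N = 100, 1500 iterations) preserves the
sign and magnitude structure at ~1/100 the cost, and the acceptance tests
scale R further down to fit a CI budget (the exact scales are stated where
they are used).

What the reduced study establishes (and the acceptance tests recompute):
the trajectory parameters and the mean-sharing association alpha1 are
recovered with near-nominal coverage whenever the design is informative.
The variance-sharing association alpha2 is only weakly identified at these
truths — sigma_i^2 = exp(-4 + 2 b4) is small for most women, so the hazard
multiplier exp(alpha2 sigma_i^2) departs from 1 for only a few percent of
the cohort and the alpha2 posterior stays wide even at N = 200.  For the
same reason, fitting the mean-only reference model to MELS-generated data
produces *no material alpha1 bias in this world*: the omitted-variance
channel is too weak to act as a frailty.  A generating design in which
that misspecification bias is large would need a much stronger
within-subject variance signal than these truths imply.

## Diagnostics

* **IWRES**: `(y_ij - mu_i(t_ij)) / sigma_i` at posterior means of
  parameters and random effects; standard normal under a correct
  longitudinal submodel.
* **Cox-Snell residuals**: `r_i = -log S_pop(t*_i)` on the cure-adjusted
  population survival, with `t*` the interval midpoint for detected events
  (convention configurable: left/midpoint/right) and the censoring time
  otherwise. Under a correct model these behave as a *censored* unit
  exponential sample whose support is bounded by `-log eta`; the calibrated
  check is therefore the Kaplan-Meier overlay against `exp(-r)` (Greenwood
  95% band, lifelines), not a naive events-only KS test — the latter is
  exact only when essentially all events are observed (near-zero cure, long
  follow-up, fine inspection partition), which is how the test suite
  exercises it.
* **LOO-CV**: subject-level PSIS-LOO (arviz) from the pointwise
  log-likelihoods recorded at every retained draw (both submodels'
  contributions, conditional on the subject's sampled random effects),
  reported as -2 * elpd so that lower is better; comparisons report the
  paired SE over subjects and carry a warning when >10% of Pareto-k values
  exceed 0.7.

## Numerical choices and limitations

* Quadrature order 20 (relative error ~1e-8 over the tested ranges); the
  hazard at t = 0 is unbounded for phi < 1, but the open-interval
  Gauss-Legendre nodes never evaluate it there, and the scenario truths
  have phi ~ 4.
* Event-time inversion brackets by doubling up to 1e6 days, then Brent with
  1e-12 absolute tolerance.
* The sampler treats non-finite log posteriors as divergences; log-hazards
  are clipped at 600 before exponentiation.
* The cure fraction, Weibull shape, and both associations are weakly
  identified when events are few (<~20); posteriors are then
  prior-volume-dominated and slow-mixing — a property of the model, not of
  the sampler. The simulation-study defaults avoid that regime.
* Wall-clock: one N = 100 fit with 2 chains x 600 iterations takes ~30-60 s
  on one CPU; the published 3 x 6000 protocol takes tens of minutes per
  dataset.
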