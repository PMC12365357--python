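# melscure

Bayesian joint modelling of a nonlinear longitudinal biomarker and an
interval-censored survival outcome with a cured subpopulation.

The motivating problem comes from early-pregnancy monitoring: serial
log10 beta-HCG hormone measurements during the first trimester, and the
time of early fetal loss. Three complications are handled jointly:

* the hormone trajectory is nonlinear — a three-parameter logistic curve
  mu_i(t) = a_i1 / (1 + exp{-(t - a_i2)/a_i3}) with log-normal
  subject-specific parameters a_ik = exp(theta_k + b_ik);
* the exact time of fetal death is unknown — only a detection interval
  (t_L, t_R] around it, typically 10 days wide;
* most women never miscarry — a mixture-cure model with cure probability
  eta = 1/(1 + e^{-nu}).

Susceptible women face the Weibull proportional hazard

    h_i(t) = phi t^{phi-1} exp{ lam + alpha1 * mu_i(t) + alpha2 * sigma_i^2 },

linked to the longitudinal process through the current mean mu_i(t) and —
the distinguishing feature — the woman's own residual variance sigma_i^2
from a mixed-effects location-scale (MELS) longitudinal submodel,
sigma_i = exp(theta4 + b_i4). Setting alpha2 = 0 with a common sigma gives
the standard "share the mean only" joint model (the *reference* variant).
Negative alpha1 means high hormone levels protect against fetal loss;
positive alpha2 means erratic trajectories signal risk.

Inference is fully Bayesian: a hand-written NUTS sampler with analytic
gradients plus a conjugate inverse-Wishart Gibbs step for the
random-effects covariance (no external probabilistic-programming backend
is required). The package also provides a scenario simulator, a
bias/coverage simulation-study harness, IWRES and Cox-Snell residual
diagnostics, and PSIS-LOO model comparison. See `docs/methods.md` for the
model, the sampler, and the design decisions.

## Worked example

```python
import warnings
from melscure import FitConfig, fit, posterior_summary, scenario_II, simulate_dataset
from melscure.inference import TABLE_TRANSFORMS
from melscure.diagnostics import loo_compare

# a synthetic cohort of 100 women from the MELS generating truth
dataset = simulate_dataset(scenario_II(N=100, visits_range=(1, 4), seed=42))

fits = {}
for variant in ("mels", "reference"):
    cfg = FitConfig(model_variant=variant, chains=2, iterations=800,
                    max_treedepth=7, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # short chains -> Rhat warnings
        fits[variant] = fit(dataset, cfg)

print(posterior_summary(fits["mels"], transforms=TABLE_TRANSFORMS,
                        params=["alpha1", "alpha2"]))
cmp = loo_compare(fits["mels"], fits["reference"])
print(f"LOO deviance: mels {cmp.loo_a:.0f}, reference {cmp.loo_b:.0f}")
```

Output from this exact script (one CPU, ~2 minutes):

```
  parameter       mean       q2.5      q97.5
0    alpha1  -0.222680  -0.946331   0.451031
1    alpha2   4.135243 -10.495250  19.536540
2       a10   4.557787   4.397830   4.728867
3       a20  13.214752  11.605733  14.911526
4       a30   7.787719   6.441329   9.358483
LOO deviance: mels 194, reference 240
```

Reading it: the plateau `a10 = exp(theta1)` is ~4.6 log10 units, the
half-rise day `a20` ~13 days, the rise time-scale `a30` ~7.8 days — the
population beta-HCG curve. The association parameters are weakly
identified at N = 100 with 1-4 visits per woman (wide credible intervals;
the generating truth alpha1 = -0.4, alpha2 = 3.1 lies inside both) — at
the published cohort size and chain length the posterior tightens around
negative alpha1. The MELS variant is preferred by leave-one-out
cross-validation (lower deviance-scale LOO is better).

## Command line

```bash
melscure simulate --config scenario.yaml --seed 7 --out data/
melscure fit --longitudinal data/longitudinal.csv --survival data/survival.csv \
         --variant mels --seed 1 --out fit/
melscure diagnose --longitudinal data/longitudinal.csv --survival data/survival.csv \
         --variant mels --seed 1 --out diag/
melscure simstudy --config study.yaml --seed 1 --out study/
```

where `scenario.yaml` is e.g. `{preset: scenario_II, N: 100, visits_range: [1, 4]}`.
Every command logs its seed and config hash and writes a JSON run manifest.

## Simulation study

`melscure.simstudy.run_study` reproduces the bias / 95%-coverage analysis:
simulate R cohorts under a scenario truth, fit one or both variants, and
tabulate per-parameter bias and coverage with Monte-Carlo standard errors
(non-convergent replicates are excluded and counted). The full protocol
(R = 1000, N = 200) is `FULL_PROTOCOL`; reduced replication preserves the
structure of the analysis at a fraction of the cost. The trajectory
parameters theta and the mean-sharing association alpha1 are recovered
with near-nominal coverage when the design is informative; the
variance-sharing association alpha2 is weakly identified at these sample
sizes (see `docs/methods.md` for what the simulated world does and does
not establish).

## Acceptance script

`scripts/acceptance.py` runs the package end to end from scratch: it
simulates a Scenario II cohort, fits both model variants by MCMC, prints
convergence diagnostics, posterior summaries (the a_k0 / alpha layout),
the IWRES and Cox-Snell summaries, and the LOO comparison, then writes its
JSON result file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
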