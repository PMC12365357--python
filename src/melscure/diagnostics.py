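"""Goodness-of-fit and model comparison for fitted joint models.

* IWRES — individual weighted residuals (y - mu_hat)/sigma_hat at the
  posterior means of parameters and subject random effects; approximately
  standard normal under a correct longitudinal submodel.
* Cox-Snell residuals — r_i = -log S_pop(t*_i) using the cure-adjusted
  population survival; unit-exponential under a correct survival submodel.
  Interval-censored subjects are imputed at a configurable endpoint
  (midpoint by default) and treated as events; right-censored subjects
  remain censored.
* Kaplan-Meier overlay of the residuals against exp(-r) with a Greenwood
  95% band.
* Subject-level PSIS-LOO comparison on the deviance scale (-2 * elpd,
  lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import (DEFAULT_QUAD_ORDER, Parameters, RandomEffects, Subject,
                    error_sd, logistic_mean, population_survival)

__all__ = ["ResidualSet", "iwres", "cox_snell", "km_overlay",
           "loo_deviance", "loo_compare", "LooComparison",
           "params_at_posterior_mean"]


@dataclass
class ResidualSet:
    """Survival residuals: one Cox-Snell residual per subject."""

    residuals: np.ndarray
    event: np.ndarray          # True where treated as an observed event
    subject_ids: list[str]


PointEstimate = tuple[Parameters, Sequence[RandomEffects]]


def params_at_posterior_mean(draws: PosteriorDraws) -> PointEstimate:
    """Plug-in estimate: posterior means of globals, Sigma and subject effects."""
    mean = {n: float(draws.get(n).mean()) for n in draws.param_names}
    p = 4 if draws.variant == "mels" else 3
    Sigma = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            Sigma[i, j] = Sigma[j, i] = mean[f"Sigma[{i+1},{j+1}]"]
    common = dict(theta1=mean["theta1"], theta2=mean["theta2"],
                  theta3=mean["theta3"], nu=mean["nu"], lam=mean["lam"],
                  phi=mean["phi"], alpha1=mean["alpha1"], Sigma=Sigma)
    if draws.variant == "mels":
        params = Parameters(theta4=mean["theta4"], alpha2=mean["alpha2"], **common)
    else:
        params = Parameters(sigma=mean["sigma"], **common)
    b_mean = draws.random_effects_mean()
    return params, [RandomEffects.from_array(b) for b in b_mean]


def _resolve(estimate: Union[PosteriorDraws, PointEstimate]) -> PointEstimate:
    if isinstance(estimate, PosteriorDraws):
        return params_at_posterior_mean(estimate)
    return estimate


def iwres(dataset: Sequence[Subject],
          estimate: Union[PosteriorDraws, PointEstimate]) -> np.ndarray:
    """Individual weighted residuals for every longitudinal observation.

    ``estimate`` is either a fitted :class:`PosteriorDraws` (posterior means
    are plugged in) or an explicit ``(Parameters, [RandomEffects])`` pair.
    """
    params, b_list = _resolve(estimate)
    if len(b_list) != len(dataset):
        raise ValueError("need one random-effects vector per subject")
    out = []
    for subject, b in zip(dataset, b_list):
        sd = error_sd(params, b, subject.n_obs)
        out.append((subject.y - logistic_mean(params, b, subject.times)) / sd)
    return np.concatenate(out)


def cox_snell(dataset: Sequence[Subject],
              estimate: Union[PosteriorDraws, PointEstimate],
              convention: Literal["midpoint", "left", "right"] = "midpoint",
              quad_order: int = DEFAULT_QUAD_ORDER) -> ResidualSet:
    """Cox-Snell residuals under interval censoring and cure.

    r_i = -log{eta + (1-eta) S(t*_i)} with t* the imputed event time
    (interval endpoint convention configurable) for interval-censored
    subjects, or the censoring time for right-censored subjects.
    """
    params, b_list = _resolve(estimate)
    if len(b_list) != len(dataset):
        raise ValueError("need one random-effects vector per subject")
    res, event, ids = [], [], []
    for subject, b in zip(dataset, b_list):
        if subject.censoring == "interval":
            tstar = {"midpoint": 0.5 * (subject.t_left + subject.t_right),
                     "left": subject.t_left,
                     "right": subject.t_right}[convention]
            event.append(True)
        else:
            tstar = subject.t_cens
            event.append(False)
        s = population_survival(tstar, params, b, subject.n_obs, quad_order)
        res.append(-np.log(max(s, 1e-300)))
        ids.append(subject.id)
    return ResidualSet(residuals=np.asarray(res), event=np.asarray(event),
                       subject_ids=ids)


def km_overlay(residuals: ResidualSet) -> pd.DataFrame:
    """Kaplan-Meier curve of the residuals with Greenwood 95% CI and the
    unit-exponential reference exp(-r), as a tidy curve table."""
    from lifelines import KaplanMeierFitter
    if residuals.residuals.size < 1:
        raise ValueError("need at least one residual")
    km = KaplanMeierFitter()
    km.fit(residuals.residuals, event_observed=residuals.event)
    tl = km.survival_function_.index.to_numpy()
    ci = km.confidence_interval_survival_function_
    return pd.DataFrame({
        "residual": tl,
        "km": km.survival_function_.iloc[:, 0].to_numpy(),
        "ci_lower": ci.iloc[:, 0].to_numpy(),
        "ci_upper": ci.iloc[:, 1].to_numpy(),
        "unit_exponential": np.exp(-tl),
    })


@dataclass
class LooComparison:
    loo_a: float                 # -2 * elpd, lower is better
    loo_b: float
    elpd_diff: float             # elpd_a - elpd_b
    se_diff: float
    preferred: Literal["A", "B"]
    warnings: list[str]


def _pointwise_elpd(draws: PosteriorDraws) -> tuple[np.ndarray, float, list[str]]:
    import arviz as az
    idata = az.from_dict(
        posterior={"lp_dummy": draws.pointwise.mean(axis=2)},
        log_likelihood={"subject": draws.pointwise},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    msgs = []
    k = np.asarray(res.pareto_k)
    frac_bad = float(np.mean(k > 0.7))
    if frac_bad > 0.1:
        msgs.append(f"{frac_bad:.0%} of Pareto-k values exceed 0.7; "
                    "PSIS-LOO may be unreliable")
    return np.asarray(res.loo_i), float(res.elpd_loo), msgs


def loo_deviance(draws: PosteriorDraws) -> float:
    """PSIS-LOO on the deviance scale (-2 * elpd_loo); lower is better."""
    _, elpd, _ = _pointwise_elpd(draws)
    return -2.0 * elpd


def loo_compare(draws_a: PosteriorDraws, draws_b: PosteriorDraws) -> LooComparison:
    """Compare two fitted models by subject-level PSIS-LOO.

    Both fits must cover the same subjects.  The difference SE is the
    paired SE over subjects of the pointwise elpd differences.
    """
    if draws_a.subject_ids != draws_b.subject_ids:
        raise ValueError("LOO comparison requires identical subject sets")
    ei_a, elpd_a, warn_a = _pointwise_elpd(draws_a)
    ei_b, elpd_b, warn_b = _pointwise_elpd(draws_b)
    diff = ei_a - ei_b
    se = float(np.sqrt(len(diff) * np.var(diff, ddof=1))) if len(diff) > 1 else np.nan
    return LooComparison(
        loo_a=-2.0 * elpd_a, loo_b=-2.0 * elpd_b,
        elpd_diff=float(elpd_a - elpd_b), se_diff=se,
        preferred="A" if elpd_a >= elpd_b else "B",
        warnings=warn_a + warn_b,
    )
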