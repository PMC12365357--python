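"""Joint log-likelihood, priors, and their composition identities."""

import numpy as np
import pytest
from scipy import stats

from melscure.likelihood import (joint_loglik, log_prior, longitudinal_loglik,
                                 survival_loglik)
from melscure.model import (Parameters, RandomEffects, Subject,
                            cumulative_hazard, cure_fraction, hazard,
                            logistic_mean)


def _subject_at_mean(params, b, times, censoring="right", **kw):
    y = logistic_mean(params, b, np.asarray(times))
    return Subject(id="s", times=np.asarray(times, dtype=float), y=y,
                   censoring=censoring, **kw)


class TestLongitudinalLoglik:
    def test_zero_residual_single_obs(self, params_I):
        s = _subject_at_mean(params_I, RandomEffects(), [20.0], t_cens=20.0)
        assert longitudinal_loglik(s, params_I, RandomEffects()) == pytest.approx(
            np.log(1.0 / (0.25 * np.sqrt(2 * np.pi))))

    def test_sum_of_pointwise_densities(self, params_II, rng):
        b = RandomEffects(*rng.normal(0, 0.2, 4))
        times = np.array([15.0, 42.0])
        y = logistic_mean(params_II, b, times) + rng.normal(0, 0.3, 2)
        s = Subject(id="s", times=times, y=y, censoring="right", t_cens=42.0)
        sd = np.exp(-2.0 + b.b4)
        oracle = stats.norm.logpdf(y, logistic_mean(params_II, b, times), sd).sum()
        assert longitudinal_loglik(s, params_II, b) == pytest.approx(oracle, rel=1e-12)

    def test_doubling_sigma_costs_log2_per_obs(self):
        base = dict(theta1=1.5, theta2=2.7, theta3=1.9, lam=-14.5, phi=4.0,
                    alpha1=-0.6, nu=0.0, Sigma=np.eye(3) * 0.1)
        p1 = Parameters(sigma=0.2, **base)
        p2 = Parameters(sigma=0.4, **base)
        b = RandomEffects()
        s = _subject_at_mean(p1, b, [10.0, 30.0, 55.0], t_cens=55.0)
        ll1 = longitudinal_loglik(s, p1, b)
        ll2 = longitudinal_loglik(s, p2, b)
        assert ll1 - ll2 == pytest.approx(3 * np.log(2.0))


class TestSurvivalLoglik:
    def test_whole_line_interval(self, params_I):
        s = _subject_at_mean(params_I, RandomEffects(), [20.0],
                             censoring="interval", t_left=0.0, t_right=1e4)
        eta = cure_fraction(params_I.nu)
        assert survival_loglik(s, params_I, RandomEffects()) == pytest.approx(
            np.log(1 - eta), abs=1e-9)

    def test_right_censored_at_zero_is_uninformative(self, params_I):
        s = _subject_at_mean(params_I, RandomEffects(), [20.0], t_cens=0.0)
        # Subject demands t_cens set; at t=0 population survival is 1
        assert survival_loglik(s, params_I, RandomEffects()) == pytest.approx(0.0)

    def test_interval_matches_quadrature_oracle(self, params_I):
        # composition with an independent fine-grid integrator
        b = RandomEffects()
        s = _subject_at_mean(params_I, b, [25.0], censoring="interval",
                             t_left=30.0, t_right=40.0)
        eta = cure_fraction(params_I.nu)
        H = []
        for t in (30.0, 40.0):
            u = np.linspace(1e-9, t, 200_000)
            H.append(np.trapezoid(hazard(u, params_I, b), u))
        oracle = np.log((1 - eta) * (np.exp(-H[0]) - np.exp(-H[1])))
        assert survival_loglik(s, params_I, b) == pytest.approx(oracle, rel=1e-6)

    def test_degenerate_interval_raises(self, params_I):
        s = _subject_at_mean(params_I, RandomEffects(), [20.0],
                             censoring="interval", t_left=1e5, t_right=2e5)
        with pytest.raises(FloatingPointError):
            survival_loglik(s, params_I, RandomEffects())

    def test_cure_monotonicity(self, params_I):
        # raising nu helps right-censored subjects, hurts event subjects
        b = RandomEffects()
        kw = dict(theta1=1.5, theta2=2.7, theta3=1.9, sigma=0.25, lam=-14.5,
                  phi=4.0, alpha1=-0.6, Sigma=np.diag([0.02, 0.08, 0.17]))
        lo, hi = Parameters(nu=0.2, **kw), Parameters(nu=1.5, **kw)
        s_int = _subject_at_mean(lo, b, [25.0], censoring="interval",
                                 t_left=30.0, t_right=40.0)
        s_right = _subject_at_mean(lo, b, [25.0], t_cens=25.0)
        assert survival_loglik(s_int, hi, b) < survival_loglik(s_int, lo, b)
        assert survival_loglik(s_right, hi, b) > survival_loglik(s_right, lo, b)

    def test_interval_shrinks_to_density(self, params_I):
        # [S(tL) - S(tR)] / width -> f(t) as the interval shrinks
        b = RandomEffects()
        t0, w = 35.0, 1e-4
        s = _subject_at_mean(params_I, b, [25.0], censoring="interval",
                             t_left=t0, t_right=t0 + w)
        eta = cure_fraction(params_I.nu)
        ll = survival_loglik(s, params_I, b)
        f = hazard(t0, params_I, b) * np.exp(-cumulative_hazard(t0, params_I, b))
        assert ll == pytest.approx(np.log((1 - eta) * f * w), abs=1e-3)


class TestLogPrior:
    def test_location_parameters_at_mode(self):
        p = Parameters(theta1=0, theta2=0, theta3=0, sigma=1.0, lam=0, phi=1.0,
                       alpha1=0, nu=0, Sigma=np.eye(3))
        lp = log_prior(p)
        # six Normal(0,10^2) terms at their mode
        normal_part = 6 * stats.norm.logpdf(0, scale=10.0)
        halfcauchy_part = 2 * stats.halfcauchy.logpdf(1.0)
        iw_part = stats.invwishart.logpdf(np.eye(3), df=5, scale=np.eye(3))
        assert lp == pytest.approx(normal_part + halfcauchy_part + iw_part, rel=1e-12)

    def test_mels_prior_against_density_oracles(self, params_II):
        lp = log_prior(params_II)
        locs = [1.5, 2.7, 1.9, params_II.nu, -14.7, -0.4, -2.0, 3.1]
        expected = (stats.norm.logpdf(locs, scale=10.0).sum()
                    + stats.halfcauchy.logpdf(3.9)
                    + stats.invwishart.logpdf(np.diag([0.02, 0.07, 0.1, 0.6]),
                                              df=6, scale=np.eye(4)))
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_reference_prior_is_on_sigma_squared(self, params_I):
        # half-Cauchy placed on sigma^2, not on sigma
        lp = log_prior(params_I)
        locs = [1.5, 2.7, 1.9, params_I.nu, -14.5, -0.6]
        expected = (stats.norm.logpdf(locs, scale=10.0).sum()
                    + stats.halfcauchy.logpdf(4.0)
                    + stats.halfcauchy.logpdf(0.25**2)
                    + stats.invwishart.logpdf(np.diag([0.02, 0.08, 0.17]),
                                              df=5, scale=np.eye(3)))
        assert lp == pytest.approx(expected, rel=1e-12)


class TestJointLoglik:
    def test_empty_dataset(self, params_I):
        total, pw = joint_loglik([], params_I, [])
        assert total == 0.0 and pw == []

    def test_additivity_and_composition(self, params_I, toy_subjects):
        bs = [RandomEffects(0.05, -0.1, 0.02), RandomEffects(-0.03, 0.08, 0.0)]
        total, pw = joint_loglik(toy_subjects, params_I, bs)
        assert total == pytest.approx(sum(p.loglik for p in pw), abs=1e-10)
        for subj, b, p in zip(toy_subjects, bs, pw):
            hand = (longitudinal_loglik(subj, params_I, b)
                    + survival_loglik(subj, params_I, b))
            assert p.loglik == pytest.approx(hand, abs=1e-10)
            assert p.subject_id == subj.id

    def test_mismatched_lengths(self, params_I, toy_subjects):
        with pytest.raises(ValueError):
            joint_loglik(toy_subjects, params_I, [RandomEffects()])


class TestVectorizedEngineAgreement:
    """The sampler's packed/jitted likelihood must match the reference API."""

    @pytest.mark.parametrize("variant", ["reference", "mels"])
    def test_pointwise_agreement(self, variant, params_I, params_II, rng):
        from melscure._posterior import (pack_dataset, natural_to_unconstrained,
                                         _likelihood_terms, _likelihood_terms_fast)
        from melscure.simulate import scenario_I, scenario_II, simulate_dataset

        scen = scenario_I(N=20, seed=5) if variant == "reference" else \
            scenario_II(N=20, seed=6)
        params = params_I if variant == "reference" else params_II
        data = simulate_dataset(scen)
        packed = pack_dataset(data, variant)
        p = packed.n_re
        b = 0.25 * rng.standard_normal((20, p))
        nat = dict(theta1=params.theta1, theta2=params.theta2,
                   theta3=params.theta3, nu=params.nu, lam=params.lam,
                   phi=params.phi, alpha1=params.alpha1)
        if variant == "mels":
            nat.update(theta4=params.theta4, alpha2=params.alpha2)
        else:
            nat["sigma"] = params.sigma
        g = natural_to_unconstrained(nat, packed)

        ref = _likelihood_terms(g, b, packed, want_grad=True)
        fast = _likelihood_terms_fast(g, b, packed, want_grad=True)
        np.testing.assert_allclose(fast[0], ref[0], rtol=1e-9)
        np.testing.assert_allclose(fast[1], ref[1], rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(fast[2], ref[2], rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(fast[3], ref[3], rtol=1e-9)

        # and the reference path itself must match the public API
        bs = [RandomEffects.from_array(bi) for bi in b]
        total, pw = joint_loglik(data, params, bs)
        np.testing.assert_allclose(ref[3], [p_.loglik for p_ in pw], rtol=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        from melscure._posterior import (pack_dataset, natural_to_unconstrained,
                                         logpost_and_grad)
        from melscure.simulate import scenario_II, simulate_dataset

        data = simulate_dataset(scenario_II(N=8, seed=3))
        packed = pack_dataset(data, "mels")
        L = np.linalg.cholesky(np.diag([0.02, 0.07, 0.1, 0.6]))
        nat = dict(theta1=1.4, theta2=2.6, theta3=1.8, theta4=-1.9, nu=0.7,
                   lam=-13.0, phi=3.5, alpha1=-0.3, alpha2=2.0)
        q = np.concatenate([natural_to_unconstrained(nat, packed),
                            0.3 * rng.standard_normal(8 * 4)])
        lp, grad = logpost_and_grad(q, L, packed)
        eps = 1e-6
        idx = rng.choice(q.size, size=15, replace=False)
        for i in idx:
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            num = (logpost_and_grad(qp, L, packed)[0]
                   - logpost_and_grad(qm, L, packed)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)
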