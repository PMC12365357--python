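"""Scenario simulator: latent draws, event-time inversion, visit schedules,
detection intervals, and whole-dataset determinism."""

import numpy as np
import pytest
from scipy import stats

from melscure.model import RandomEffects, cumulative_hazard, cure_fraction
from melscure.simulate import (ScenarioConfig, apply_interval_censoring,
                               draw_subject_latents, make_visits_and_responses,
                               scenario_I, scenario_II, simulate_dataset,
                               simulate_event_time)


class TestLatents:
    def test_covariance_matches_sigma(self, rng):
        # Scenario I diagonal covariance recovered from sample moments
        config = scenario_I(N=1)
        draws = np.array([draw_subject_latents(config, rng)[0].as_array(3)
                          for _ in range(20_000)])
        var = draws.var(axis=0, ddof=1)
        target = np.array([0.02, 0.08, 0.17])
        se = target * np.sqrt(2 / 20_000)  # SE of a normal sample variance
        assert np.all(np.abs(var - target) < 3.5 * se)

    def test_cure_proportion(self, rng):
        config = scenario_II(N=1, cure_fraction_true=0.7)
        cured = np.array([draw_subject_latents(config, rng)[1]
                          for _ in range(10_000)])
        assert abs(cured.mean() - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 10_000)

    def test_extreme_nu_all_susceptible(self, rng, params_I):
        from dataclasses import replace as dc_replace
        import melscure.simulate as sim
        params = sim._scenario_params_I(cure_nu=-30.0)
        config = ScenarioConfig(params=params, N=1)
        assert not any(draw_subject_latents(config, rng)[1] for _ in range(200))


class TestEventTime:
    def test_weibull_closed_form(self, rng):
        # with sharing off, T = (E * exp(-lam))^(1/phi) exactly
        from melscure.model import Parameters
        p = Parameters(theta1=1.5, theta2=2.7, theta3=1.9, sigma=0.25,
                       lam=-13.0, phi=3.0, alpha1=0.0, nu=0.0,
                       Sigma=np.eye(3) * 0.1)
        b = RandomEffects()
        for seed in range(20):
            r1 = np.random.default_rng(seed)
            T = simulate_event_time(p, b, 2, r1)
            E = np.random.default_rng(seed).exponential()
            assert T == pytest.approx((E * np.exp(13.0)) ** (1 / 3.0), rel=1e-6)

    def test_monotone_coupling(self, params_I):
        # larger exponential deviate -> larger event time
        from melscure.simulate import _invert_cumhaz
        b = RandomEffects(0.1, -0.1, 0.0)
        Es = np.sort(np.random.default_rng(1).exponential(size=10))
        Ts = [_invert_cumhaz(E, params_I, b, 2) for E in Es]
        assert np.all(np.diff(Ts) > 0)

    def test_root_tolerance(self, params_II, rng):
        from melscure.simulate import _invert_cumhaz
        b = RandomEffects(*rng.normal(0, 0.2, 4))
        for _ in range(10):
            E = rng.exponential()
            T = _invert_cumhaz(E, params_II, b, 3)
            assert abs(cumulative_hazard(T, params_II, b, 3) - E) < 1e-8 * max(E, 1)

    def test_ks_against_analytic_cdf(self, params_I):
        # Kolmogorov-Smirnov agreement with 1 - exp(-H(t)) at fixed b
        b = RandomEffects()
        rng = np.random.default_rng(12345)
        T = np.array([simulate_event_time(params_I, b, 2, rng)
                      for _ in range(10_000)])
        grid = np.linspace(1e-3, T.max() * 1.05, 4000)
        cg = 1.0 - np.exp(-cumulative_hazard(grid, params_I, b, 2))
        res = stats.ks_1samp(T, lambda t: np.interp(t, grid, cg))
        assert res.pvalue > 0.01


class TestVisitsAndResponses:
    def test_zero_noise_recovers_mean(self, rng):
        import melscure.simulate as sim
        from melscure.model import Parameters, logistic_mean
        p = Parameters(theta1=1.5, theta2=2.7, theta3=1.9, theta4=-30.0,
                       alpha2=0.0, lam=-14.7, phi=3.9, alpha1=-0.4, nu=0.85,
                       Sigma=np.eye(4) * 0.01)
        config = ScenarioConfig(params=p, N=1, visits_range=(3, 3))
        b = RandomEffects()
        s = make_visits_and_responses(config, p, b, None, rng)
        np.testing.assert_allclose(s.y, logistic_mean(p, b, s.times), atol=1e-10)

    def test_cured_subject_right_censored_at_study_end(self, rng):
        config = scenario_I(N=1, visits_range=(2, 5))
        s = make_visits_and_responses(config, config.params, RandomEffects(),
                                      None, rng)
        assert s.censoring == "right"
        assert s.t_cens == config.study_end
        assert s.n_obs == len(s.times)  # all scheduled visits retained

    def test_visit_counts_uniform_for_cured(self, rng):
        config = scenario_I(N=1, visits_range=(1, 4))
        counts = np.array([
            make_visits_and_responses(config, config.params, RandomEffects(),
                                      None, rng).n_obs
            for _ in range(4000)])
        observed = np.bincount(counts, minlength=5)[1:5]
        res = stats.chisquare(observed)
        assert res.pvalue > 0.001

    def test_visits_truncated_before_event_when_enabled(self, rng):
        # realism mode: no hormone measurement at or after fetal death
        config = scenario_I(N=1, visits_range=(4, 4), truncate_visits=True)
        s = make_visits_and_responses(config, config.params, RandomEffects(),
                                      45.0, rng)
        assert np.all(s.times < 45.0)

    def test_full_schedule_kept_by_default(self, rng):
        config = scenario_I(N=1, visits_range=(4, 4))
        s = make_visits_and_responses(config, config.params, RandomEffects(),
                                      45.0, rng)
        assert s.n_obs == 4
        assert s.censoring == "interval"
        assert s.t_left < 45.0 <= s.t_right


class TestIntervalCensoring:
    def test_containment_first_window(self):
        config = scenario_I(N=1)
        assert apply_interval_censoring(35.0, 30.0, config) == (30.0, 40.0)

    def test_partition_cell_beyond_first_window(self):
        # the recorded interval is the detection cell containing T, so the
        # interval mass equals the probability of the observation
        config = scenario_I(N=1)
        assert apply_interval_censoring(55.0, 30.0, config) == (50.0, 60.0)

    def test_cell_truncated_at_next_scheduled_visit(self):
        config = scenario_I(N=1)
        assert apply_interval_censoring(55.0, 30.0, config, next_visit=57.0) \
            == (50.0, 57.0)

    def test_containment_always(self, rng):
        config = scenario_I(N=1)
        for _ in range(200):
            last = rng.uniform(5, 60)
            T = last + rng.exponential(12)
            tL, tR = apply_interval_censoring(T, last, config)
            assert tL < T <= tR
            assert tR - tL <= config.detection_window + 1e-12

    def test_rejects_event_before_visit(self):
        config = scenario_I(N=1)
        with pytest.raises(ValueError):
            apply_interval_censoring(25.0, 30.0, config)


class TestSimulateDataset:
    def test_seeded_determinism(self):
        config = scenario_II(N=40, seed=99)
        d1 = simulate_dataset(config)
        d2 = simulate_dataset(config)
        for a, b in zip(d1, d2):
            assert a.id == b.id and a.censoring == b.censoring
            np.testing.assert_array_equal(a.times, b.times)
            np.testing.assert_array_equal(a.y, b.y)
            assert (a.t_left, a.t_right, a.t_cens) == (b.t_left, b.t_right, b.t_cens)

    def test_latent_event_in_recorded_interval(self):
        config = scenario_II(N=300, seed=7)
        subjects, truths = simulate_dataset(config, return_truth=True)
        for s, t in zip(subjects, truths):
            if s.censoring == "interval":
                assert not t.cured
                assert s.t_left < t.event_time <= s.t_right
            else:
                assert s.t_cens == config.study_end
                if not t.cured:  # susceptible, event beyond the study end
                    assert t.event_time > s.t_cens

    def test_row_count_bounds(self):
        config = scenario_I(N=200, visits_range=(1, 4), seed=3)
        data = simulate_dataset(config)
        rows = sum(s.n_obs for s in data)
        assert 200 <= rows <= 800

    def test_censoring_class_proportions(self):
        # share of interval-censored = (1 - eta) * P(detected before the
        # last scheduled visit); check against the latent truth record
        config = scenario_II(N=2000, visits_range=(1, 4), seed=21)
        subjects, truths = simulate_dataset(config, return_truth=True)
        n_int = sum(s.censoring == "interval" for s in subjects)
        detected = [(not t.cured) and t.event_time is not None
                    and s.censoring == "interval"
                    for s, t in zip(subjects, truths)]
        assert n_int == sum(detected)
        # all cured subjects are right-censored
        assert all(s.censoring == "right"
                   for s, t in zip(subjects, truths) if t.cured)
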