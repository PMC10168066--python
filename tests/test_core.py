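"""Deterministic system- and observation-model mathematics."""

import numpy as np
import pytest
from scipy import stats

from rhizostate import core


class TestOverallTemperatureEffect:
    @pytest.mark.parametrize("bst, bsm, sm, expected", [
        (1.0, 0.05, 20.0, 2.0),
        (0.7, 0.03, 0.0, 0.7),  # zero-moisture identity
        (0.435, 0.0, 33.0, 0.435),  # no interaction: effect equals beta_st
    ])
    def test_values(self, bst, bsm, sm, expected):
        assert core.overall_temperature_effect(bst, bsm, sm) == \
            pytest.approx(expected, abs=1e-12)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        sm = rng.uniform(0, 50)
        lhs = core.overall_temperature_effect(2 * a + b, 3 * a - b, sm)
        np.testing.assert_allclose(
            lhs, a * (2 + 3 * sm) + b * (1 - sm), atol=1e-12)

    def test_negative_moisture_rejected(self):
        with pytest.raises(ValueError):
            core.overall_temperature_effect(1.0, 0.01, -5.0)


class TestExogenousEffect:
    def test_log_identity(self):
        assert core.exogenous_effect(1.0, np.e + 4.0, 4.0) == \
            pytest.approx(1.0, rel=1e-12)

    def test_direct_evaluation(self):
        # 1.5 * ln 10 = 3.45387764
        assert core.exogenous_effect(1.5, 14.0, 4.0) == \
            pytest.approx(1.5 * np.log(10.0), rel=1e-12)
        assert core.exogenous_effect(1.5, 14.0, 4.0) == \
            pytest.approx(3.45388, abs=1e-5)

    def test_unit_difference_is_zero(self):
        assert core.exogenous_effect(2.0, 5.0, 4.0) == pytest.approx(0.0)

    def test_domain_error_at_threshold(self):
        with pytest.raises(ValueError):
            core.exogenous_effect(1.0, 4.0, 4.0)
        with pytest.raises(ValueError):
            core.exogenous_effect(1.0, 4.005, 4.0)  # inside the eps margin

    def test_sign_flip_below_unit_difference(self):
        assert core.exogenous_effect(2.0, 4.5, 4.0) < 0
        assert core.exogenous_effect(2.0, 6.0, 4.0) > 0


class TestGrowthRate:
    def test_below_threshold_is_baseline(self):
        beta = core.growth_rate(le=3.0, beta_st=5.0, beta_sm=1.0, sm=40.0,
                                st=2.0, stmin=4.0, beta_base=0.001)
        assert beta == pytest.approx(0.001)

    def test_above_threshold_value(self):
        # le=0, bext=1, ST-stmin=e: exp(0 + ln e) + 0.001 = e + 0.001
        beta = core.growth_rate(0.0, 1.0, 0.0, 10.0, 4.0 + np.e, 4.0, 0.001)
        assert beta == pytest.approx(np.e + 0.001, rel=1e-12)

    def test_large_negative_le_limit(self):
        beta = core.growth_rate(-700.0, 1.0, 0.0, 10.0, 20.0, 4.0, 0.002)
        assert beta == pytest.approx(0.002, rel=1e-9)

    def test_always_at_least_baseline(self):
        rng = np.random.default_rng(1)
        st = rng.uniform(0, 30, 50)
        beta = core.growth_rate(rng.normal(-6, 2, 50), rng.normal(1, 0.3, 50),
                                rng.normal(0.02, 0.01, 50),
                                rng.uniform(5, 45, 50), st, 4.0, 1e-4)
        assert np.all(beta >= 1e-4)

    def test_threshold_continuity(self):
        # approaching stmin from above with bext = 1: beta -> beta_base
        for d in (1e-3, 1e-6):
            # eps margin must be below the approach distance
            beta = core.growth_rate(0.0, 1.0, 0.0, 0.0, 4.0 + d, 4.0, 0.01,
                                    eps=d / 10)
            assert beta == pytest.approx(0.01 + d, rel=1e-6)

    def test_monotone_in_temperature(self):
        st = np.linspace(4.5, 30, 100)
        beta = core.growth_rate(-5.0, 1.2, 0.02, 25.0, st, 4.0, 1e-4)
        assert np.all(np.diff(beta) > 0)


class TestMeanProduction:
    @pytest.mark.parametrize("beta, b, expected", [
        (0.0, 5.0, 0.0),
        (0.01, 2.0, 0.02),
    ])
    def test_values(self, beta, b, expected):
        assert core.mean_production(beta, b) == pytest.approx(expected)

    def test_below_threshold_form(self):
        assert core.mean_production(1e-4, 3.7) == pytest.approx(3.7e-4)

    def test_invalid(self):
        with pytest.raises(ValueError):
            core.mean_production(0.01, 0.0)
        with pytest.raises(ValueError):
            core.mean_production(-0.01, 1.0)


class TestPropagateBiomass:
    def test_hand_step(self):
        assert core.propagate_biomass(1.0, 0.01, 0.005, 10.0) == \
            pytest.approx(1.05, rel=1e-14)

    def test_balanced_identity(self):
        assert core.propagate_biomass(3.2, 0.01, 0.01, 7.0) == \
            pytest.approx(3.2)

    def test_equals_explicit_mass_balance(self):
        b, beta, gamma, v = 2.3, 0.012, 0.004, 11.0
        pv = beta * b * v
        mv = gamma * b * v
        assert core.propagate_biomass(b, beta, gamma, v) == \
            pytest.approx(b + pv - mv, rel=1e-15)

    def test_positivity_violation(self):
        with pytest.raises(core.PositivityError):
            core.propagate_biomass(1.0, 0.0, 0.2, 10.0)


class TestBiomassTrajectory:
    def test_two_step_hand_recursion(self, tiny_forcing):
        periods = tiny_forcing.periods[:3]
        forcing = core.EnvForcingSeries(
            periods=periods, st=[10.0, 10.0, 10.0], sm=[20.0] * 3,
            v=[10.0, 10.0, 11.0])
        sc = core.ScalarParams(b1=1.0, gamma=0.005, beta_base=1e-9,
                               stmin=4.0)
        # choose le so that beta = {0.01, 0.02, .}: beta=exp(le+bext*ln 6)
        le = np.log(np.array([0.01, 0.02, 0.02]))
        traj = core.biomass_trajectory(1.0, le, [0.0] * 3, [0.0] * 3,
                                       forcing, sc)
        np.testing.assert_allclose(traj.b, [1.0, 1.05, 1.2075], rtol=1e-6)

    def test_all_below_threshold_gives_baseline_production(self):
        periods = [(2011, 1, "early"), (2011, 1, "mid"), (2011, 1, "late")]
        forcing = core.EnvForcingSeries(periods=periods, st=[1.0, 2.0, 3.0],
                                        sm=[20.0] * 3, v=[10, 10, 11])
        sc = core.ScalarParams(b1=2.0, gamma=0.001, beta_base=5e-4, stmin=4.0)
        traj = core.biomass_trajectory(2.0, [0.0] * 3, [1.0] * 3, [0.1] * 3,
                                       forcing, sc)
        np.testing.assert_allclose(traj.p, sc.beta_base * traj.b, rtol=1e-14)

    def test_zero_mortality_closed_form(self):
        periods = [(2011, 1, "early"), (2011, 1, "mid"), (2011, 1, "late")]
        forcing = core.EnvForcingSeries(periods=periods, st=[1.0, 1.0, 1.0],
                                        sm=[20.0] * 3, v=[10, 10, 11])
        bb = 1e-3
        sc = core.ScalarParams(b1=1.0, gamma=0.0, beta_base=bb, stmin=4.0)
        traj = core.biomass_trajectory(1.0, [-700.0] * 3, [0.0] * 3,
                                       [0.0] * 3, forcing, sc)
        expected = [1.0, 1.0 + bb * 10, (1.0 + bb * 10) ** 2]
        np.testing.assert_allclose(traj.b, expected, rtol=1e-12)

    def test_positivity_error_carries_index(self, tiny_forcing):
        sc = core.ScalarParams(b1=1.0, gamma=0.2, beta_base=1e-6, stmin=50.0)
        with pytest.raises(core.PositivityError) as err:
            core.biomass_trajectory(1.0, [-9.0] * tiny_forcing.T,
                                    [0.0] * tiny_forcing.T,
                                    [0.0] * tiny_forcing.T, tiny_forcing, sc)
        assert err.value.index == 0

    def test_mass_balance_invariant(self, tiny_study):
        traj, forcing = tiny_study.truth, tiny_study.forcing
        beta = traj.p / traj.b
        pv = traj.p[:-1] * forcing.v[:-1]
        mv = traj.scalars.gamma * traj.b[:-1] * forcing.v[:-1]
        gap = traj.b[-1] - traj.b[0] - np.sum(pv - mv)
        assert abs(gap) <= 1e-12 * max(1.0, abs(traj.b[-1]))
        del beta


class TestHierGammaLoglik:
    def test_closed_form_density(self):
        # Gamma(shape=2, rate=2) at 1: f = 4 e^-2, ln f = ln 4 - 2
        obs = core.ProductionObservations(t=[0], s=[0], c=[0], value=[1.0],
                                          S=1, C=1)
        pw, _ = core.hier_gamma_loglik(obs, ps=np.array([[1.0]]),
                                       lambda_t=np.array([2.0]),
                                       lambda_s=np.array([[2.0]]),
                                       p_path=np.array([1.0]))
        assert pw[0] == pytest.approx(np.log(4.0) - 2.0, rel=1e-12)
        assert pw[0] == pytest.approx(-0.61371, abs=1e-5)

    def test_missing_records_contribute_nothing(self, micro_instance):
        forcing, scalars, traj, disp, obs = micro_instance
        pw, sl = core.hier_gamma_loglik(obs, disp.ps, disp.lambda_t,
                                        disp.lambda_s, traj.p)
        assert len(pw) == obs.n_obs  # only observed records scored
        # dropping one record removes exactly its term
        sub = core.ProductionObservations(t=obs.t[1:], s=obs.s[1:],
                                          c=obs.c[1:], value=obs.value[1:],
                                          S=obs.S, C=obs.C)
        pw2, _ = core.hier_gamma_loglik(sub, disp.ps, disp.lambda_t,
                                        disp.lambda_s, traj.p)
        assert pw[1:].sum() == pytest.approx(pw2.sum(), rel=1e-12)

    def test_hierarchy_mean_is_p(self):
        # grand mean of simulated F targets p for any dispersion
        rng = np.random.default_rng(3)
        p, lam_t, lam_s, n = 0.02, 40.0, 60.0, 100_000
        ps = rng.gamma(lam_t * p, 1 / lam_t, n)
        F = rng.gamma(lam_s * ps, 1 / lam_s)
        se = F.std(ddof=1) / np.sqrt(n)
        assert abs(F.mean() - p) < 3 * se

    def test_invalid_parameters(self, micro_instance):
        _, _, traj, disp, obs = micro_instance
        with pytest.raises(ValueError):
            core.hier_gamma_loglik(obs, disp.ps, -disp.lambda_t,
                                   disp.lambda_s, traj.p)

    def test_zero_censoring_below_offset_density(self):
        obs = core.ProductionObservations(t=[0, 0], s=[0, 0], c=[0, 1],
                                          value=[0.0, 0.01], S=1, C=2)
        ps = np.array([[0.01]])
        lt = np.array([500.0])
        ls = np.array([[500.0]])
        p = np.array([0.01])
        pw_c, _ = core.hier_gamma_loglik(obs, ps, lt, ls, p,
                                         zero_rule="censor")
        # censored mass equals the gamma CDF at half the min positive value
        expected = np.log(stats.gamma.cdf(0.005, a=5.0, scale=1 / 500.0))
        assert pw_c[0] == pytest.approx(expected, rel=1e-9)


class TestRandomWalkLogprior:
    def test_single_step_standard_normal(self):
        lp = core.random_walk_logprior([0.0, 1.0], 1.0, init_sd=None)
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5, rel=1e-12)
        assert lp == pytest.approx(-1.41894, abs=1e-5)

    def test_constant_path(self):
        T, sigma = 7, 0.3
        lp = core.random_walk_logprior(np.zeros(T), sigma, 0.0, 2.0)
        expected = (T - 1) * stats.norm.logpdf(0, 0, sigma) \
            + stats.norm.logpdf(0, 0, 2.0)
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma_zero_increments(self):
        T = 5
        lp1 = core.random_walk_logprior(np.zeros(T), 0.5, init_sd=None)
        lp2 = core.random_walk_logprior(np.zeros(T), 1.0, init_sd=None)
        assert lp2 - lp1 == pytest.approx(-(T - 1) * np.log(2), rel=1e-12)


class TestLogPosterior:
    @staticmethod
    def _naive_oracle(forcing, scalars, traj, disp, obs, priors):
        """Unvectorized re-derivation: plain loops, scipy densities only."""
        T, S = forcing.T, obs.S
        lp = 0.0
        for t in range(T):
            for s in range(S):
                a = disp.lambda_t[t] * traj.p[t]
                lp += stats.gamma.logpdf(disp.ps[t, s], a,
                                         scale=1.0 / disp.lambda_t[t])
        for i in range(obs.n_obs):
            t, s = obs.t[i], obs.s[i]
            a = disp.lambda_s[t, s] * disp.ps[t, s]
            lp += stats.gamma.logpdf(obs.value[i], a,
                                     scale=1.0 / disp.lambda_s[t, s])
        for path, sig, m, sd in ((traj.le, scalars.sigma_le, priors.le1_mean,
                                  priors.le1_sd),
                                 (traj.beta_st, scalars.sigma_st, 0.0,
                                  priors.coef1_sd),
                                 (traj.beta_sm, scalars.sigma_sm, 0.0,
                                  priors.coef1_sd)):
            lp += stats.norm.logpdf(path[0], m, sd)
            for t in range(1, T):
                lp += stats.norm.logpdf(path[t], path[t - 1], sig)
        lp += stats.halfnorm.logpdf(scalars.gamma, scale=priors.gamma_scale)
        lp += stats.halfnorm.logpdf(scalars.beta_base,
                                    scale=priors.beta_base_scale)
        for s in (scalars.sigma_le, scalars.sigma_st, scalars.sigma_sm):
            lp += stats.halfnorm.logpdf(s, scale=priors.sigma_scale)
        # dispersion prior: half-Cauchy on the implied shape, so the density
        # over the rate is HC(lam * mean) * mean
        for t in range(T):
            lp += stats.halfcauchy.logpdf(disp.lambda_t[t] * traj.p[t],
                                          scale=priors.lambda_scale)
            lp += np.log(traj.p[t])
        for t in range(T):
            for s in range(S):
                lp += stats.halfcauchy.logpdf(
                    disp.lambda_s[t, s] * disp.ps[t, s],
                    scale=priors.lambda_scale)
                lp += np.log(disp.ps[t, s])
        lp += stats.norm.logpdf(scalars.b1, priors.b1_mean,
                                priors.b1_cv * priors.b1_mean)
        return lp

    def test_agrees_with_naive_oracle(self, micro_instance):
        forcing, scalars, traj, disp, obs = micro_instance
        priors = core.PriorConfig(b1_mean=1.2)
        lp, pw = core.log_posterior(traj, disp, obs, forcing, priors)
        oracle = self._naive_oracle(forcing, scalars, traj, disp, obs,
                                    priors)
        assert lp == pytest.approx(oracle, abs=1e-10)

    def test_pointwise_table_sums_to_likelihood_component(
            self, micro_instance):
        forcing, scalars, traj, disp, obs = micro_instance
        priors = core.PriorConfig(b1_mean=1.2)
        lp, pw = core.log_posterior(traj, disp, obs, forcing, priors)
        pw2, sl = core.hier_gamma_loglik(obs, disp.ps, disp.lambda_t,
                                         disp.lambda_s, traj.p)
        np.testing.assert_allclose(pw, pw2, rtol=1e-12)

    def test_empty_observations_reduce_to_prior(self, micro_instance):
        forcing, scalars, traj, disp, obs = micro_instance
        priors = core.PriorConfig(b1_mean=1.2)
        empty = core.ProductionObservations(t=[], s=[], c=[], value=[],
                                            S=obs.S, C=obs.C)
        lp_empty, _ = core.log_posterior(traj, disp, empty, forcing, priors)
        lp_full, pw = core.log_posterior(traj, disp, obs, forcing, priors)
        assert lp_full - lp_empty == pytest.approx(pw.sum(), rel=1e-9)

    def test_inadmissible_returns_neg_inf(self, micro_instance):
        forcing, scalars, traj, disp, obs = micro_instance
        bad = core.LatentTrajectory(
            le=traj.le, beta_st=traj.beta_st, beta_sm=traj.beta_sm,
            b=traj.b, p=traj.p,
            scalars=scalars.replace(gamma=0.5))
        lp, pw = core.log_posterior(bad, disp, obs, forcing, priors=
                                    core.PriorConfig(b1_mean=1.2))
        assert lp == -np.inf and pw is None


class TestDomainTypes:
    def test_forcing_year_length_validation(self):
        # a full year with a wrong interval total must be rejected
        from rhizostate.preprocess import DekadCalendar
        periods = DekadCalendar.periods_between("2011-01-01", "2011-12-31")
        v = np.array([DekadCalendar.length_days(p) for p in periods],
                     dtype=float)
        core.EnvForcingSeries(periods=periods, st=np.zeros(36),
                              sm=np.zeros(36), v=v)  # valid
        v_bad = v.copy()
        v_bad[0] += 1
        with pytest.raises(ValueError):
            core.EnvForcingSeries(periods=periods, st=np.zeros(36),
                                  sm=np.zeros(36), v=v_bad)

    def test_duplicate_observation_keys_rejected(self):
        with pytest.raises(ValueError):
            core.ProductionObservations(t=[0, 0], s=[0, 0], c=[1, 1],
                                        value=[0.1, 0.2], S=1, C=2)

    def test_latent_trajectory_invariants(self, tiny_study):
        tiny_study.truth.validate(tiny_study.forcing)
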