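"""Discretization exactness, the batched matrix exponential, the joint
state/parameter particle filter and maximum-likelihood calibration."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from optoloop import (DEFAULT_DOSE_RESPONSE, DisturbanceEvent, ModelParams,
                      PFConfig, Plant, batched_expm, discretize,
                      discretize_adaptive, fit_model_ml, measurement_to_fold,
                      pf_init, pf_update, simulate_characterization)
from optoloop.estimation import batched_discretize_adaptive
from optoloop.gene_plant import fold_matrices


def _random_params(rng):
    f = rng.lognormal(0.0, 0.4, 4)
    return ModelParams(d_r=0.0956 * f[0], d_p=0.0214 * f[1],
                       b_r=0.0965 * f[2], k_m=0.0116 * f[3])


class TestDiscretize:
    def test_mrna_decay_mode_at_nominal(self, nominal):
        model = discretize(nominal)
        assert model.Ad[0, 0] == pytest.approx(math.exp(-0.0956 * 10.0),
                                               rel=1e-12)
        assert model.Ad[0, 0] == pytest.approx(0.3845, abs=1e-4)

    def test_transition_matrix_tends_to_identity(self, nominal):
        for T_s, tol in [(1.0, 0.2), (0.01, 2e-3), (1e-4, 2e-5)]:
            m = discretize(ModelParams(T_s=T_s))
            assert np.linalg.norm(m.Ad - np.eye(3)) < tol

    def test_eigenvalues_inside_unit_interval(self, rng):
        for _ in range(10):
            m = discretize(_random_params(rng))
            ev = np.linalg.eigvals(m.Ad)
            assert np.all((ev.real > 0) & (ev.real < 1))
            assert np.allclose(ev.imag, 0.0)

    def test_rest_state_fixed_without_input(self, nominal):
        m = discretize(nominal)
        np.testing.assert_allclose(m.step(np.zeros(3), 0.0, 0.0), 0.0,
                                   atol=1e-15)

    def test_one_step_matches_ode_on_random_draws(self, rng):
        """ZOH propagation equals adaptive ODE integration over one
        sampling period to 1e-9 relative accuracy (20 draws)."""
        for _ in range(20):
            p = _random_params(rng)
            m = discretize(p)
            x0 = rng.normal(0.0, 0.5, 3)
            u = rng.uniform(0.0, 2.0)
            A, B = fold_matrices(p)
            sol = solve_ivp(lambda t, x: A @ x + B * u, (0.0, p.T_s), x0,
                            rtol=1e-12, atol=1e-14, method="LSODA")
            np.testing.assert_allclose(m.step(x0, u), sol.y[:, -1],
                                       rtol=1e-9, atol=1e-12)

    def test_parameter_continuity(self, nominal):
        m0 = discretize(nominal)
        eps = 1e-6
        m1 = discretize(ModelParams(d_r=nominal.d_r * (1 + eps),
                                    d_p=nominal.d_p, b_r=nominal.b_r,
                                    k_m=nominal.k_m))
        assert np.linalg.norm(m1.Ad - m0.Ad) < 1e-5


class TestAdaptiveModel:
    def test_coincides_with_nominal_at_baseline(self, nominal):
        a = discretize_adaptive(nominal, nominal)
        b = discretize(nominal)
        np.testing.assert_allclose(a.Ad, b.Ad, atol=1e-12)
        np.testing.assert_allclose(a.Bd, b.Bd, atol=1e-12)
        np.testing.assert_allclose(a.fd, 0.0, atol=1e-12)

    def test_dilution_change_shifts_steady_level(self):
        """With production frozen at the calibration rates, raising d_p
        lowers the un-induced steady level by the same factor as the
        continuous-culture balance predicts."""
        base = ModelParams(d_p=math.log(2.0) / 38.0)
        fast = ModelParams(d_p=math.log(2.0) / 25.0)
        m = discretize_adaptive(fast, base)
        x_fix = np.linalg.solve(np.eye(3) - m.Ad, m.fd)
        gamma = ((base.d_p / fast.d_p)
                 * (base.d_p + base.k_m) / (fast.d_p + fast.k_m))
        assert 1.0 + x_fix[2] == pytest.approx(gamma, rel=1e-9)

    def test_batched_matches_dense(self, rng):
        base = ModelParams().as_vector()
        thetas = np.exp(np.log(base) + 0.3 * rng.standard_normal((50, 4)))
        Ad, Bd, fd = batched_discretize_adaptive(thetas, base, 10.0)
        for i in (0, 17, 49):
            dense = discretize_adaptive(ModelParams.from_vector(thetas[i]),
                                        ModelParams())
            np.testing.assert_allclose(Ad[i], dense.Ad, rtol=1e-12)
            np.testing.assert_allclose(Bd[i], dense.Bd, rtol=1e-12)
            np.testing.assert_allclose(fd[i], dense.fd, rtol=1e-10,
                                       atol=1e-14)


class TestBatchedExpm:
    def test_agrees_with_scipy_on_random_stacks(self, rng):
        M = rng.normal(0.0, 1.0, (40, 5, 5))
        E = batched_expm(M)
        for i in range(0, 40, 7):
            np.testing.assert_allclose(E[i], expm(M[i]), rtol=1e-10,
                                       atol=1e-12)

    def test_identity_and_zero(self):
        Z = np.zeros((3, 4, 4))
        np.testing.assert_allclose(batched_expm(Z),
                                   np.broadcast_to(np.eye(4), (3, 4, 4)))


def _simulate_measurements(plant, U_seq, rng, noise=0.03):
    """True fold-change outputs of a plant under a commanded sequence with
    the one-step actuation delay, plus multiplicative measurement noise."""
    x = np.ones(3)
    ys = []
    for k in range(len(U_seq)):
        y = x[2]
        if noise > 0:
            y *= 1.0 + noise * rng.standard_normal()
        ys.append(y)
        x = plant.advance(x, U_seq[k - 1] if k >= 1 else 0.0, k * 10.0, 10.0)
    return np.array(ys)


class TestParticleFilter:
    CFG = PFConfig(n_particles=800)

    def test_weights_normalized_and_ess_in_range(self, nominal, rng):
        ens = pf_init(nominal, self.CFG, rng)
        dr = DEFAULT_DOSE_RESPONSE
        for k in range(15):
            ens = pf_update(ens, dr(20.0), 1.0 + 0.05 * k, self.CFG)
            assert np.isclose(ens.weights.sum(), 1.0, atol=1e-12)
            assert 1.0 <= ens.ess <= ens.n

    def test_missing_measurement_propagates_without_reweighting(self,
                                                                nominal, rng):
        ens = pf_init(nominal, self.CFG, rng)
        w_before = ens.weights.copy()
        ens = pf_update(ens, 0.5, None, self.CFG)
        np.testing.assert_array_equal(ens.weights, w_before)

    def test_posterior_collapses_on_truth_with_tight_likelihood(self,
                                                                nominal, rng):
        cfg = PFConfig(n_particles=400, sigma_meas_rel=1e-4,
                       sigma_meas_floor=1e-4, sigma_process=1e-6,
                       init_param_spread=1e-6, init_state_spread=0.05)
        model = discretize(nominal)
        x = np.zeros(3)
        ens = pf_init(nominal, cfg, rng)
        ens.states[0] = x           # one particle holds the exact truth
        err = None
        for k in range(12):
            x = model.step(x, 1.0)
            ens = pf_update(ens, 1.0, 1.0 + x[2], cfg)
            err = abs(ens.state_estimate()[2] - (1.0 + x[2]))
        assert err < 1e-3

    def test_state_estimate_converges_on_noise_free_data(self, nominal, rng):
        model = discretize(nominal)
        cfg = PFConfig(n_particles=1500, sigma_meas_rel=0.01)
        x = np.zeros(3)
        ens = pf_init(nominal, cfg, rng)
        errs = []
        for k in range(40):
            x = model.step(x, 1.0)
            ens = pf_update(ens, 1.0, 1.0 + x[2], cfg)
            errs.append(abs(ens.state_estimate()[2] - (1.0 + x[2])))
        assert np.mean(errs[-10:]) < np.mean(errs[:5])
        assert np.mean(errs[-10:]) < 0.03

    def test_disturbance_estimate_consistent_with_zero(self, nominal, rng):
        plant = Plant()
        U = np.tile([10.0, 25.0, 5.0, 40.0], 10)
        ys = _simulate_measurements(plant, U, rng)
        ens = pf_init(nominal, self.CFG, rng)
        dr = plant.dose_response
        d_hat = []
        for k in range(1, len(ys)):   # ys[k] is the post-propagation output
            u_last = dr(U[k - 2]) if k >= 2 else 0.0
            ens = pf_update(ens, u_last, ys[k], self.CFG)
            d_hat.append(ens.d_estimate())
        assert abs(np.mean(d_hat[10:])) <= 2.0 * ens.d_posterior_sd() + 0.05

    def test_disturbance_step_moves_estimate_toward_truth(self, nominal,
                                                          rng):
        model = discretize(nominal)
        cfg = PFConfig(n_particles=1500)
        x = np.zeros(3)
        ens = pf_init(nominal, cfg, rng)
        d_true, d_hat = 0.0, []
        for k in range(45):
            if k == 20:
                d_true = 0.5
            x = model.step(x, 0.5 + d_true)
            y = (1.0 + x[2]) * (1.0 + 0.02 * rng.standard_normal())
            ens = pf_update(ens, 0.5, y, cfg)
            d_hat.append(ens.d_estimate())
        before = np.mean(d_hat[14:20])
        within10 = d_hat[29]
        assert within10 > before + 0.03            # clearly moving up
        assert np.mean(d_hat[35:]) > within10 - 0.05

    def test_tracks_dilution_rate_change_in_medium_shift(self):
        """Medium-shift plant under an exciting input: the posterior d_p
        moves from the M9 value toward the LB value after the shift."""
        plant = Plant(params=ModelParams(d_p=math.log(2.0) / 38.0),
                      events=(DisturbanceEvent(kind="medium_shift",
                                               onset=300.0,
                                               new_doubling_time=25.0),))
        cfg = PFConfig(n_particles=2000)
        rng = np.random.default_rng(0)
        gen = np.random.default_rng(99)
        U = gen.choice([0.0, 5.0, 12.0, 30.0, 60.0], size=90)
        ys = _simulate_measurements(plant, U, rng)
        ens = pf_init(plant.params, cfg, rng)
        dr = plant.dose_response
        est = []
        for k in range(1, len(ys)):
            u_last = dr(U[k - 2]) if k >= 2 else 0.0
            ens = pf_update(ens, u_last, ys[k], cfg)
            est.append(ens.param_estimate().d_p)
        pre = np.mean(est[20:30])
        post = np.mean(est[-15:])
        assert post > pre + 0.001     # toward ln2/25 = 0.0277

    def test_fixed_seed_is_reproducible(self, nominal):
        def run():
            rng = np.random.default_rng(5)
            ens = pf_init(nominal, self.CFG, rng)
            for k in range(10):
                ens = pf_update(ens, 0.8, 1.0 + 0.05 * k, self.CFG)
            return ens.state_estimate(), ens.d_estimate()
        (s1, d1), (s2, d2) = run(), run()
        np.testing.assert_array_equal(s1, s2)
        assert d1 == d2


class TestMLFit:
    def test_recovers_rates_from_noise_free_data(self, nominal):
        data = simulate_characterization(nominal)
        fitted, diag = fit_model_ml(data, seed=0, n_starts=2)
        np.testing.assert_allclose(fitted.as_vector(), nominal.as_vector(),
                                   rtol=0.01)
        assert diag["rmse"] < 1e-6

    def test_trace_order_does_not_matter(self, nominal):
        data = simulate_characterization(nominal, noise_rel=0.05,
                                         rng=np.random.default_rng(3))
        from optoloop import CharacterizationSet
        flipped = CharacterizationSet(traces=data.traces[::-1])
        a, _ = fit_model_ml(data, seed=0, n_starts=2)
        b, _ = fit_model_ml(flipped, seed=0, n_starts=2)
        np.testing.assert_allclose(a.as_vector(), b.as_vector(), rtol=1e-5)

    def test_constant_input_flags_non_identifiability(self, nominal):
        from optoloop import CharacterizationSet, CharacterizationTrace
        t = np.arange(20) * 10.0
        tr = CharacterizationTrace(time_min=t, U_pct=np.zeros(20),
                                   G_fold=np.ones(20))
        _, diag = fit_model_ml(CharacterizationSet(traces=(tr,)), seed=0,
                               n_starts=2)
        assert diag["non_identifiable_warning"]

    def test_dc_gain_ratio_recovers_under_noise(self, nominal):
        """The dose-response gain b_r/d_r -- the quantity the controller
        relies on -- is sharply identified even at 5% noise."""
        data = simulate_characterization(nominal, noise_rel=0.05,
                                         rng=np.random.default_rng(8))
        fitted, _ = fit_model_ml(data, seed=0, n_starts=2)
        assert fitted.dc_gain == pytest.approx(nominal.dc_gain, rel=0.05)

    def test_requires_enough_samples(self, nominal):
        from optoloop import CharacterizationSet, CharacterizationTrace
        t = np.arange(5) * 10.0
        tr = CharacterizationTrace(time_min=t, U_pct=np.zeros(5),
                                   G_fold=np.ones(5))
        with pytest.raises(ValueError):
            fit_model_ml(CharacterizationSet(traces=(tr,)))


def test_measurement_to_fold_divides_by_baseline():
    assert measurement_to_fold(0.3, 0.15) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        measurement_to_fold(0.3, 0.0)
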