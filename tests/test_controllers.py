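"""PI law arithmetic, gain scheduling, growth PI, and the MPC optimizer
against a brute-force enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optoloop import (DEFAULT_DOSE_RESPONSE, MPCConfig, ModelParams, PIConfig,
                      PIState, ReferenceProfile, ScheduleStage,
                      apply_gain_schedule, discretize, growth_pi_step, mpc_step,
                      pi_step)
from optoloop.controllers import (GROWTH_PI_CONFIG, _prediction_matrices,
                                  evaluate_schedule_trigger, mpc_predict_cost)


class TestPI:
    def test_zero_error_rest_gives_zero_input(self):
        u, state = pi_step(PIConfig(), PIState(), 2.0, 2.0)
        assert u == 0.0 and state.u_I == 0.0

    def test_published_gain_arithmetic(self):
        # K_P=80, K_I=8, e=0.5: integral update first (u_I'=4), then u=44
        cfg = PIConfig(K_P=80.0, K_I=8.0)
        u, state = pi_step(cfg, PIState(), 2.5, 2.0)
        assert state.u_I == pytest.approx(4.0)
        assert u == pytest.approx(44.0)

    def test_output_and_integral_clamps(self):
        cfg = PIConfig(K_P=80.0, K_I=8.0, clamp=(0.0, 30.0))
        state = PIState()
        for _ in range(30):          # persistent large positive error
            u, state = pi_step(cfg, state, 3.0, 1.0)
        assert state.u_I == 30.0 and u == 100.0
        for _ in range(60):          # persistent large negative error
            u, state = pi_step(cfg, state, 1.0, 3.0)
        assert state.u_I == 0.0 and u == 0.0

    def test_measurement_failure_reuses_previous(self):
        cfg = PIConfig(K_P=80.0, K_I=8.0)
        u1, state = pi_step(cfg, PIState(), 2.5, 2.0)
        u2, state2 = pi_step(cfg, state, 2.5, None)
        _, expect = pi_step(cfg, state, 2.5, 2.0)
        assert u2 == expect.last_input
        with pytest.raises(ValueError):
            pi_step(cfg, PIState(), 2.0, None)

    @given(st.floats(-2.0, 2.0), st.floats(0.0, 30.0))
    def test_emitted_input_always_within_limits(self, e, u_I):
        cfg = PIConfig(K_P=80.0, K_I=8.0)
        u, state = pi_step(cfg, PIState(u_I=u_I), 2.0 + e, 2.0)
        assert 0.0 <= u <= 100.0
        assert cfg.clamp[0] <= state.u_I <= cfg.clamp[1]


class TestGainSchedule:
    CFG = PIConfig(K_P=80.0, K_I=8.0,
                   schedule=(ScheduleStage(K_P=160.0, K_I=20.0,
                                           at_time=240.0),))

    def test_time_trigger_swaps_once(self):
        state = PIState()
        trig, state = evaluate_schedule_trigger(self.CFG, state, 250.0, 2.0,
                                                2.0, 0.1)
        state = apply_gain_schedule(self.CFG, state, trig)
        assert self.CFG.gains_at_stage(state.stage) == (160.0, 20.0)
        state2 = apply_gain_schedule(self.CFG, state, True)  # no more stages
        assert state2.stage == state.stage

    def test_no_trigger_keeps_gains(self):
        state = PIState()
        trig, state = evaluate_schedule_trigger(self.CFG, state, 100.0, 2.0,
                                                2.0, 0.1)
        assert not trig
        assert self.CFG.gains_at_stage(state.stage) == (80.0, 8.0)

    def test_in_band_trigger_needs_consecutive_samples(self):
        cfg = PIConfig(schedule=(ScheduleStage(160.0, 20.0,
                                               in_band_samples=3),))
        state = PIState()
        fired = []
        for y in [2.0, 2.0, 3.0, 2.0, 2.0, 2.0]:
            trig, state = evaluate_schedule_trigger(cfg, state, 0.0, y, 2.0,
                                                    0.1)
            fired.append(trig)
        assert fired == [False, False, False, False, False, True]

    def test_bumpless_transfer_at_zero_error(self):
        state = PIState(u_I=12.0)
        u_before, s1 = pi_step(self.CFG, state, 2.0, 2.0)
        switched = apply_gain_schedule(self.CFG, state, True)
        u_after, _ = pi_step(self.CFG, switched, 2.0, 2.0)
        assert switched.u_I == state.u_I
        assert u_after == u_before


class TestGrowthPI:
    def test_zero_error_passes_integral_and_complements_red(self):
        ug, ur, _ = growth_pi_step(GROWTH_PI_CONFIG, PIState(u_I=30.0),
                                   0.009, 0.009)
        assert ug == 30.0 and ur == 70.0

    def test_published_growth_gain_arithmetic(self):
        # K_P=6000, K_I=45, e=0.001/min: u_I'=0.045, u_green=6.045
        ug, ur, state = growth_pi_step(GROWTH_PI_CONFIG, PIState(),
                                       0.010, 0.009)
        assert state.u_I == pytest.approx(0.045)
        assert ug == pytest.approx(6.045)
        assert ug + ur == 100.0

    def test_integral_saturates_in_printed_interval(self):
        state = PIState(u_I=5.0)
        for _ in range(100):
            ug, ur, state = growth_pi_step(GROWTH_PI_CONFIG, state,
                                           0.003, 0.014)
        assert state.u_I == 0.0 and ug == 0.0 and ur == 100.0
        for _ in range(500):
            ug, ur, state = growth_pi_step(GROWTH_PI_CONFIG, state,
                                           0.014, 0.003)
        assert state.u_I == 60.0


def _instance(seed, horizon=3, du_weight=0.0):
    rng = np.random.default_rng(seed)
    model = discretize(ModelParams())
    cfg = MPCConfig(horizon=horizon, du_weight=du_weight)
    x0 = rng.normal(0.0, 0.3, 3)
    pend = rng.uniform(0.0, 1.0)
    d = rng.uniform(-0.2, 0.2)
    ref = rng.uniform(1.0, 2.1, horizon)
    return model, cfg, x0, pend, d, ref


class TestMPC:
    def test_cost_matches_bruteforce_on_grid_instance(self):
        """With the reference generated by a known on-grid sequence, the
        exact optimum lies on the grid and both routes find cost zero."""
        model = discretize(ModelParams())
        cfg = MPCConfig(horizon=3, du_weight=0.0)
        levels = np.linspace(0.0, cfg.u_cap_fold, 5)
        true_seq = np.array([levels[3], levels[1], levels[4]])
        x0, pend, d = np.array([0.1, 0.05, 0.02]), 0.3, 0.05
        F, pv, Phi, dist, drift = _prediction_matrices(model, 3)
        ref = 1.0 + F @ x0 + pv * pend + dist * d + drift + Phi @ true_seq
        _, _, _, info = mpc_step(cfg, model, x0, pend, d, ref)
        brute = min(mpc_predict_cost(model, cfg, x0, pend, d, ref,
                                     np.array(s))
                    for s in itertools.product(levels, repeat=3))
        assert abs(info["cost"] - brute) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_optimizer_never_beaten_by_enumeration(self, seed):
        model, cfg, x0, pend, d, ref = _instance(seed, du_weight=1e-3)
        _, _, _, info = mpc_step(cfg, model, x0, pend, d, ref)
        levels = np.linspace(0.0, cfg.u_cap_fold, 5)
        brute = min(mpc_predict_cost(model, cfg, x0, pend, d, ref,
                                     np.array(s))
                    for s in itertools.product(levels, repeat=3))
        assert info["cost"] <= brute + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_intensity_capped_at_60(self, seed):
        model, cfg, x0, pend, d, ref = _instance(seed, horizon=4,
                                                 du_weight=1e-3)
        U, u0, _, _ = mpc_step(cfg, model, x0, pend, d, ref)
        assert 0.0 <= U <= 60.0
        assert 0.0 <= u0 <= cfg.u_cap_fold

    def test_equilibrium_on_reachable_reference_is_feasible(self):
        model = discretize(ModelParams())
        cfg = MPCConfig(horizon=6)
        gain = ModelParams().dc_gain
        ref = np.full(6, 2.0)
        u_eq = (2.0 - 1.0) / gain
        x_eq = np.linalg.solve(np.eye(3) - model.Ad, model.Bd * u_eq)
        _, _, _, info = mpc_step(cfg, model, x_eq, u_eq, 0.0, ref)
        band = 0.05 * 2.0
        assert np.all(np.abs(info["predicted"] - 2.0) <= band)

    def test_resolve_is_deterministic(self):
        model, cfg, x0, pend, d, ref = _instance(3, du_weight=1e-3)
        outs = {mpc_step(cfg, model, x0, pend, d, ref)[0] for _ in range(5)}
        assert len(outs) == 1

    def test_cost_nondecreasing_in_horizon(self):
        """Optimal cost over a longer horizon includes every stage of the
        shorter one plus nonnegative extra stages, so it cannot decrease."""
        rng = np.random.default_rng(11)
        model = discretize(ModelParams())
        x0 = rng.normal(0.0, 0.2, 3)
        ref = rng.uniform(1.2, 2.0, 10)
        costs = []
        for N in (2, 4, 6, 8):
            cfg = MPCConfig(horizon=N, du_weight=1e-3)
            _, _, _, info = mpc_step(cfg, model, x0, 0.5, 0.0, ref)
            costs.append(info["cost"])
        assert all(b >= a - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_pi_zero_steady_state_error_on_discretized_plant(self):
        """Positional PI with the published gains drives the error on the
        nominal ZOH plant to zero for a constant reference and fully
        rejects a constant additive input disturbance."""
        model = discretize(ModelParams())
        dr = DEFAULT_DOSE_RESPONSE
        # clamp widened so the integral can hold the post-disturbance input
        cfg = PIConfig(K_P=80.0, K_I=8.0, clamp=(0.0, 60.0))
        for d_in in (0.0, -0.08):
            x = np.zeros(3)
            state = PIState()
            U_prev = 0.0
            for k in range(500):
                y = 1.0 + x[2]
                U, state = pi_step(cfg, state, 2.0, y)
                x = model.step(x, dr(U_prev) + d_in)
                U_prev = U
            assert abs(2.0 - (1.0 + x[2])) < 0.01 * 2.0


class TestReferenceProfile:
    def test_shapes_and_band_conventions(self):
        c = ReferenceProfile(kind="constant", level=2.0)
        assert c(123.0) == 2.0 and c.band_halfwidth(0.0) == 0.1
        s = ReferenceProfile(kind="sinusoid", mean=2.0, amplitude=0.5,
                             period=120.0, band_convention="reference")
        assert s(30.0) == pytest.approx(2.5)
        assert s.band_halfwidth(30.0) == pytest.approx(0.125)
        p = ReferenceProfile(kind="piecewise_linear",
                             breakpoints=((0.0, 1.0), (100.0, 2.0)),
                             band_convention="max")
        assert p(50.0) == pytest.approx(1.5)
        assert p.band_halfwidth(50.0) == pytest.approx(0.1)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            ReferenceProfile(kind="sinusoid", mean=0.2, amplitude=0.5)
        with pytest.raises(ValueError):
            ReferenceProfile(kind="piecewise_linear", breakpoints=((0, 1),))
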