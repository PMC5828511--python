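import numpy as np
import pytest

from plumetrack.geometry import WindTunnelGeometry
from plumetrack.walkers import (
    CenterlineBelief,
    SurgeParams,
    WalkerParams,
    WalkerState,
    alpha_kernel,
    decay_centerline_belief,
    draw_batch_geometry,
    fit_base_walker,
    simulate_base,
    simulate_batch,
    simulate_centerline_inferring,
    simulate_surge_cast,
    step_base_walker,
    surge_force,
    update_centerline_belief,
)


class TestParams:
    def test_invalid_walker_params(self):
        with pytest.raises(ValueError):
            WalkerParams(tau=-1)
        with pytest.raises(ValueError):
            WalkerParams(dt=0.5, tau=0.42)  # dt >= tau

    def test_invalid_surge_params(self):
        with pytest.raises(ValueError):
            SurgeParams(timescale=0.0)


class TestAlphaFunction:
    def test_unit_peak_at_timescale(self):
        assert alpha_kernel(1.0) == pytest.approx(1.0)

    def test_zero_before_trigger(self):
        assert alpha_kernel(-0.5) == 0.0
        assert alpha_kernel(0.0) == 0.0

    def test_peak_amplitude_and_time(self):
        # single trigger at t0: force peaks at exactly A at t0 + timescale
        t = np.arange(0, 1.0, 1e-4)
        a = surge_force(t[:, None], np.array([[0.1]]), np.array([[0.8]]), 0.07)
        assert a.max() == pytest.approx(0.8, abs=1e-6)
        assert t[np.argmax(a)] == pytest.approx(0.1 + 0.07, abs=1e-3)

    def test_superposition(self):
        t = np.linspace(0, 1, 500)
        both = surge_force(t[:, None], np.array([[0.1, 0.3]]),
                           np.array([[0.8, 0.5]]), 0.07)
        one = surge_force(t[:, None], np.array([[0.1]]), np.array([[0.8]]), 0.07)
        two = surge_force(t[:, None], np.array([[0.3]]), np.array([[0.5]]), 0.07)
        np.testing.assert_allclose(both, one + two, atol=1e-12)


class TestBaseWalker:
    def test_deterministic_speed_decay(self, env):
        # eta = b = 0: after time tau the speed ratio is e^-1 up to Euler
        # bias ~ dt/(2 tau); dt = 0.005 keeps it inside 1%
        dt = 0.005
        params = WalkerParams(tau=0.42, eta=0.0, bias=0.0, dt=dt)
        state = WalkerState(np.array([0.65, 0.0, 0.0]), np.array([0.3, 0.2, 0.1]))
        v0 = np.linalg.norm(state.velocity)
        rng = np.random.default_rng(0)
        n = int(round(0.42 / dt))
        for _ in range(n):
            state = step_base_walker(state, params, rng)
        ratio = np.linalg.norm(state.velocity) / v0
        assert ratio == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_velocity_autocorrelation_time(self, env):
        # OU oracle: the discrete AR(1) recursion v' = (1-dt/tau) v + noise
        # has autocorrelation (1-dt/tau)^k; estimate tau from the simulated
        # autocorrelation and compare within 10%
        params = WalkerParams(tau=0.42, eta=1.9, bias=0.0, dt=0.01)
        big = WindTunnelGeometry(flyable_extent=(100.0, 100.0, 100.0),
                                 end_margin=1.0)
        tr = simulate_base(params, big, duration=100.0,
                           rng=np.random.default_rng(1),
                           start_position=[50.0, 0.0, 0.0])
        v = tr.velocities[:, 1]  # crosswind component, no wall effects
        v = v - v.mean()
        lags = np.arange(1, 30)
        ac = np.array([np.mean(v[:-k] * v[k:]) for k in lags]) / np.mean(v * v)
        ok = ac > 0.05
        slope = np.polyfit(lags[ok] * params.dt, np.log(ac[ok]), 1)[0]
        tau_est = -1.0 / slope
        assert tau_est == pytest.approx(0.42, rel=0.10)

    def test_crosswind_bias_centers_walk(self, env):
        params = WalkerParams(tau=0.42, eta=1.0, bias=0.5, dt=0.01)
        rng = np.random.default_rng(2)
        n_steps = np.full(40, 1500)
        starts = np.tile([0.65, 0.10, -0.10], (40, 1))
        trajs = simulate_batch(params, env, None, n_steps, starts, rng)
        tail = np.concatenate([t.positions[500:, 1] for t in trajs])
        se = tail.std() / np.sqrt(len(trajs))  # SE across trajectories
        assert abs(tail.mean()) < 3 * max(se, 0.01)

    def test_reflecting_boundaries(self, env):
        params = WalkerParams(eta=3.0, bias=0.0, dt=0.01)
        tr = simulate_base(params, env, duration=20.0,
                           rng=np.random.default_rng(3))
        tr.validate_in(env)

    def test_same_seed_bit_identical(self, env, plume):
        kw = dict(duration=3.0, start_position=[0.9, 0.0, 0.0])
        a = simulate_surge_cast(WalkerParams(), SurgeParams(), plume, env,
                                rng=np.random.default_rng(7), **kw)
        b = simulate_surge_cast(WalkerParams(), SurgeParams(), plume, env,
                                rng=np.random.default_rng(7), **kw)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)


class TestSurgeCast:
    def test_no_plume_contact_matches_base(self, env):
        # a plume far outside the walker's reach: surge term is identically 0
        from plumetrack.geometry import GaussianPlume

        far = GaussianPlume(centerline=(0.149, 0.149), sigma0=1e-4,
                            detection_threshold=0.5)
        params = WalkerParams()
        a = simulate_surge_cast(params, SurgeParams(), far, env,
                                duration=3.0, rng=np.random.default_rng(4),
                                start_position=[0.65, -0.1, -0.1])
        b = simulate_batch(params, env, None, [300], [[0.65, -0.1, -0.1]],
                           np.random.default_rng(4), mode="base")[0]
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-12)

    def test_crossing_triggers_upwind_motion(self, env, plume):
        params = WalkerParams(eta=0.3, bias=0.3)
        rng = np.random.default_rng(5)
        tr = simulate_surge_cast(params, SurgeParams(amplitude=2.0), plume, env,
                                 duration=10.0, rng=rng,
                                 start_position=[1.0, 0.1, 0.0])
        crossed = tr.concentrations.max() >= plume.detection_threshold
        if crossed:
            assert tr.positions[-1, 0] < tr.positions[0, 0]  # net upwind


class TestCenterlineBelief:
    def test_conjugate_update_closed_form(self):
        b = CenterlineBelief()  # prior var 25, obs var 4
        post = update_centerline_belief(b, (1.0, 0.1), elapsed=0.0)
        np.testing.assert_allclose(post.mean, [25 / 29, 2.5 / 29], rtol=1e-12)
        np.testing.assert_allclose(post.var, [100 / 29, 100 / 29], rtol=1e-12)

    def test_observation_at_mean_keeps_mean_shrinks_var(self):
        b = CenterlineBelief(mean=(0.05, -0.02), var=(9.0, 9.0))
        post = update_centerline_belief(b, (0.05, -0.02), elapsed=0.0)
        np.testing.assert_allclose(post.mean, b.mean, atol=1e-12)
        assert np.all(post.var < 9.0)

    def test_decay_restores_prior(self):
        b = CenterlineBelief(mean=(1.0, 1.0), var=(2.0, 2.0))
        d = decay_centerline_belief(b, 5 * b.tau_m)
        assert np.all(np.abs(d.mean) < 0.01)
        np.testing.assert_allclose(d.var, b.prior_var, rtol=0.01)

    def test_det_shrinks_with_updates(self):
        b = CenterlineBelief()
        dets = [b.det]
        for _ in range(5):
            b = update_centerline_belief(b, (0.0, 0.0), elapsed=0.0)
            dets.append(b.det)
        assert np.all(np.diff(dets) < 0)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            update_centerline_belief(CenterlineBelief(), (0, 0), elapsed=-1.0)


class TestCenterlineSimulator:
    def test_prior_determinant_limits_drive(self):
        b = CenterlineBelief()
        assert b.det == pytest.approx(625.0)  # (5 m)^2 * (5 m)^2
        kstar = 3.0
        assert kstar / b.det == pytest.approx(3.0 / 625.0)

    def test_invalid_kstar(self, env, plume):
        with pytest.raises(ValueError):
            simulate_centerline_inferring(
                WalkerParams(), CenterlineBelief(), 0.0, plume, env,
                duration=1.0, rng=np.random.default_rng(0),
            )

    def test_runs_and_stays_inside(self, env, plume):
        tr = simulate_centerline_inferring(
            WalkerParams(), CenterlineBelief(), 3.0, plume, env,
            duration=5.0, rng=np.random.default_rng(6),
        )
        tr.validate_in(env)


class TestFitBaseWalker:
    def test_requires_enough_references(self, env):
        with pytest.raises(ValueError):
            fit_base_walker([], env)

    @pytest.mark.slow
    def test_parameter_recovery(self, env):
        true = WalkerParams(tau=0.42, eta=1.9, bias=0.25)
        rng = np.random.default_rng(5)
        n_steps, starts = draw_batch_geometry(200, env, rng,
                                              duration_range=(4.0, 10.0))
        ref = simulate_batch(true, env, None, n_steps, starts, rng)
        fit = fit_base_walker(ref, env, seed=11)
        assert fit.tau == pytest.approx(0.42, rel=0.20)
        assert fit.eta == pytest.approx(1.9, rel=0.20)
        assert fit.bias == pytest.approx(0.25, rel=0.20)
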