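import numpy as np
import pytest

from plumetrack.crossings import CrossingSegment
from plumetrack.stats import (
    InsufficientDataError,
    UndefinedCorrelationError,
    crossing_number_partial_corr,
    fit_threshold_models,
    heading_concentration_curve,
    history_dependence,
    partial_correlation,
)

GRID = 0.01 * np.arange(101)


def make_seg(traj_id, number, c_peak, x0, h0, T, series, mask=None):
    series = np.asarray(series, dtype=float)
    if mask is None:
        mask = np.isfinite(series)
    return CrossingSegment(
        traj_id=traj_id, crossing_number=number, peak_index=0, c_peak=c_peak,
        x0=x0, h0=h0, T=T, heading_series=series, valid_mask=mask,
        time_grid=GRID, end_time=1.0,
    )


def model_segments(rng, n_traj=50, a_c=0.0, step=-15.0, noise=8.0,
                   timepoint_idx=30, per_traj=1):
    """Crossings drawn from the (threshold-)linear response model."""
    segs = []
    for i in range(n_traj):
        for k in range(per_traj):
            h0 = rng.uniform(60, 120)
            x0 = rng.uniform(0.3, 1.0)
            c = rng.lognormal(0, 1)
            theta = float(c >= 1.0)
            y = 0.5 * h0 + 10 * x0 + 20 + step * theta + a_c * c * theta \
                + rng.normal(0, noise)
            series = np.full(101, np.nan)
            series[0] = h0
            series[timepoint_idx] = y
            segs.append(make_seg(f"t{i}", k + 1, c, x0, h0, 1.0 + k, series))
    return segs


class TestPartialCorrelation:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(0, 1, 50)
        res = partial_correlation(x, x, n_boot=10)
        assert res.estimate == pytest.approx(1.0)

    def test_residualization_oracle(self):
        # target = z + e1, predictor = z + e2; conditioning on z leaves two
        # independent noises -> partial correlation within 3 SE of 0
        rng = np.random.default_rng(1)
        n = 10_000
        z = rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        res = partial_correlation(y, x, conditioners=[z], n_boot=50)
        assert abs(res.estimate) < 3.0 / np.sqrt(n)
        # sanity: the raw correlation is strongly positive
        assert np.corrcoef(y, x)[0, 1] > 0.4

    def test_orthogonal_conditioner_equals_pearson(self):
        rng = np.random.default_rng(2)
        n = 400
        y = rng.normal(0, 1, n)
        x = 0.5 * y + rng.normal(0, 1, n)
        # conditioner orthogonal to both (residualized against them)
        raw = rng.normal(0, 1, n)
        A = np.column_stack([np.ones(n), y, x])
        z = raw - A @ np.linalg.lstsq(A, raw, rcond=None)[0]
        res = partial_correlation(y, x, conditioners=[z], n_boot=10)
        assert res.estimate == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-10)

    def test_affine_invariance_of_conditioners(self):
        rng = np.random.default_rng(3)
        n = 300
        z = rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        r1 = partial_correlation(y, x, conditioners=[z], n_boot=10).estimate
        r2 = partial_correlation(y, x, conditioners=[5.0 * z - 3.0], n_boot=10).estimate
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_residual_raises(self):
        z = np.arange(20.0)
        with pytest.raises(UndefinedCorrelationError):
            partial_correlation(z, np.random.default_rng(0).normal(0, 1, 20),
                                conditioners=[z], n_boot=10)

    def test_bootstrap_ci_covers_estimate(self):
        rng = np.random.default_rng(4)
        n = 500
        z = rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        x = -0.5 * y + rng.normal(0, 1, n)
        groups = np.repeat(np.arange(50), 10)
        res = partial_correlation(y, x, conditioners=[z], groups=groups,
                                  n_boot=300, seed=0)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.n_groups == 50


class TestConcentrationCurve:
    def test_negative_at_300ms_on_injected_effect(self, synth_crossings):
        curve = heading_concentration_curve(synth_crossings, [0.3], n_boot=200)
        assert curve.defined[0]
        assert curve.estimates[0] < 0

    def test_t0_degenerate_reported_undefined(self, synth_crossings):
        curve = heading_concentration_curve(synth_crossings, [0.0], n_boot=10)
        assert not curve.defined[0]
        assert np.isnan(curve.estimates[0])

    def test_timepoint_beyond_grid(self, synth_crossings):
        with pytest.raises(ValueError, match="grid"):
            heading_concentration_curve(synth_crossings, [5.0])


class TestThresholdModels:
    def test_nested_sse_ordering(self):
        for seed in range(5):
            segs = model_segments(np.random.default_rng(seed))
            fb, ft, F, p = fit_threshold_models(segs, 0.3)
            assert ft.sse <= fb.sse + 1e-9
            assert F >= 0

    def test_recovers_linear_term(self):
        segs = model_segments(np.random.default_rng(0), n_traj=400, a_c=5.0,
                              noise=4.0)
        fb, ft, F, p = fit_threshold_models(segs, 0.3)
        assert p < 0.01
        assert ft.a_c == pytest.approx(5.0, rel=0.5)

    def test_crossing_counts_give_smaller_p(self):
        segs = model_segments(np.random.default_rng(1), n_traj=40, a_c=3.0,
                              per_traj=3)
        *_, p_traj = fit_threshold_models(segs, 0.3, count_mode="trajectories")
        *_, p_cross = fit_threshold_models(segs, 0.3, count_mode="crossings")
        assert p_cross <= p_traj

    def test_cth_within_observed_range(self):
        segs = model_segments(np.random.default_rng(2))
        fb, ft, *_ = fit_threshold_models(segs, 0.3)
        c = [s.c_peak for s in segs]
        assert min(c) <= fb.c_th <= max(c)
        assert min(c) <= ft.c_th <= max(c)

    def test_too_few_trajectories_raise(self):
        segs = model_segments(np.random.default_rng(3), n_traj=5)
        with pytest.raises(InsufficientDataError):
            fit_threshold_models(segs, 0.3)


class TestHistoryDependence:
    def test_perfectly_linear_delta_h_gives_zero_hstar(self):
        rng = np.random.default_rng(0)
        segs = []
        for i in range(30):
            x0 = rng.uniform(0.3, 1.0)
            T = rng.uniform(1, 20)
            h0 = rng.uniform(60, 120)
            dh = 3.0 * x0 - 0.5 * T + 2.0  # exact linear function
            series = np.full(101, h0 + dh)
            series[0] = h0
            # leave t=0 out of the check (dh(0) = 0 by construction)
            segs.append(make_seg(f"t{i}", 1 + i % 4, 1.0, x0, h0, T, series))
        res = history_dependence(segs)
        for j in range(1, 101):
            assert abs(res.early_mean[j]) < 1e-9
            assert abs(res.late_mean[j]) < 1e-9

    def test_pooled_mean_zero(self, synth_crossings):
        res = history_dependence(synth_crossings)
        scale = np.nanmax(np.abs(res.late_mean - res.early_mean)) + 1.0
        assert np.nanmax(np.abs(res.pooled_mean)) < 1e-9 * scale * 1e3

    def test_injected_attenuation_recovered(self, synth_crossings):
        res = history_dependence(synth_crossings)
        w = (res.time_grid >= 0.3) & (res.time_grid <= 0.8)
        assert np.nanmean(res.late_minus_early()[w]) > 0

    def test_single_trajectory_group_raises(self):
        segs = model_segments(np.random.default_rng(1), n_traj=5)
        # all crossings number 1 -> empty late group
        with pytest.raises(InsufficientDataError):
            history_dependence(segs)

    def test_unsupported_baseline(self, synth_crossings):
        with pytest.raises(NotImplementedError):
            history_dependence(synth_crossings, baseline="prewindow")


class TestCrossingNumberPartialCorr:
    def test_confound_absorbed_by_conditioner(self):
        # crossing number a deterministic function of T alone -> partial
        # correlation ~ 0 after conditioning on (x0, T)
        rng = np.random.default_rng(5)
        segs = []
        for i in range(120):
            T = rng.uniform(1, 20)
            number = min(5, max(1, int(T // 4) + 1))  # function of T only
            x0 = rng.uniform(0.3, 1.0)
            h0 = rng.uniform(60, 120)
            dh = 2.0 * T + rng.normal(0, 1)  # depends on T, not on number
            series = np.full(101, h0 + dh)
            series[0] = h0
            segs.append(make_seg(f"t{i}", number, 1.0, x0, h0, T, series))
        res = crossing_number_partial_corr(segs, n_boot=100)
        assert abs(res.estimate) < 0.15

    def test_smooth_decay_positive(self, env, plume):
        from plumetrack.crossings import ExclusionPolicy, apply_exclusions, \
            extract_all_crossings
        from plumetrack.synthetic import SyntheticEffects, generate_dataset

        eff = SyntheticEffects(n_traj=250, history_factor=0.6,
                               history_mode="smooth", seed=8)
        trajs = generate_dataset(eff, env, plume)
        kept = apply_exclusions(
            extract_all_crossings(trajs, plume.detection_threshold),
            ExclusionPolicy(), env,
        )
        res = crossing_number_partial_corr(kept, n_boot=100)
        assert res.estimate > 0

    def test_max_number_filter(self, synth_crossings):
        res = crossing_number_partial_corr(synth_crossings, max_number=3,
                                           n_boot=50)
        assert res.n <= sum(1 for s in synth_crossings if s.crossing_number <= 3)
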