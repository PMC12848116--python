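"""Trajectory statistics: MSD/alpha, VAC, straightness, traps, kurtosis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glassyclutch import (
    Trajectory,
    fit_alpha,
    kurtosis,
    kurtosis_ratio,
    msd_curve,
    segment_traps_steps,
    track_straightness,
    velocity_autocorrelation,
)
from glassyclutch.trajstats import MSDResult


def track(x, y=None, dt=10.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return Trajectory(times=np.arange(len(x)) * dt,
                      positions=np.column_stack([x, y]),
                      meta={"params": {"V_u": 120.0}})


class TestMSD:
    def test_ballistic_msd_is_exactly_quadratic(self):
        v, dt = 3.0, 10.0
        tr = track(v * np.arange(100) * dt)
        res = msd_curve([tr])
        assert np.allclose(res.msd, (v * res.lags) ** 2)

    def test_stationary_trajectory_msd_zero(self):
        res = msd_curve([track(np.zeros(100))])
        assert np.all(res.msd == 0.0)
        with pytest.raises(ValueError):
            fit_alpha(res)

    def test_brownian_msd_linear(self, rng):
        sigma, n = 5.0, 400
        trs = [track(*np.cumsum(rng.normal(0, sigma, (n, 2)), axis=0).T)
               for _ in range(100)]
        res = msd_curve(trs)
        k = res.lags / 10.0
        assert np.allclose(res.msd, 2 * sigma ** 2 * k, rtol=0.05)

    def test_time_and_ensemble_average_agree_for_brownian(self, rng):
        # ergodic reference: the two estimators agree within 10%
        sigma, n = 5.0, 500
        trs = [track(*np.cumsum(rng.normal(0, sigma, (n, 2)), axis=0).T)
               for _ in range(200)]
        ta = msd_curve(trs)
        eo = msd_curve(trs, from_origin=True)
        sel = slice(0, 20)
        # amplitude and fitted exponent agree within 10%
        assert np.mean(eo.msd[sel] / ta.msd[sel]) == pytest.approx(1.0, abs=0.10)
        assert fit_alpha(eo).alpha == pytest.approx(fit_alpha(ta).alpha, abs=0.1)

    def test_short_trajectories_refused(self):
        with pytest.raises(ValueError, match="64"):
            msd_curve([track(np.arange(30))])


class TestAlphaFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        lags = np.linspace(10.0, 200.0, 20)
        res = MSDResult(lags=lags, msd=3.0 * lags ** 1.7, n_cells=1)
        fit = fit_alpha(res, window=(10.0, 200.0))
        assert fit.alpha == pytest.approx(1.7, abs=1e-9)
        assert fit.mu == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ballistic_alpha_two(self):
        tr = track(2.0 * np.arange(100) * 10.0)
        assert fit_alpha(msd_curve([tr])).alpha == pytest.approx(2.0, abs=1e-9)

    def test_window_with_too_few_lags_refused(self):
        lags = np.array([10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="at least"):
            fit_alpha(MSDResult(lags=lags, msd=lags, n_cells=1))

    def test_default_window_is_first_decade(self):
        tr = track(np.arange(200, dtype=float))
        fit = fit_alpha(msd_curve([tr]))
        assert fit.fit_window == (10.0, 100.0)


class TestVAC:
    def test_ballistic_fully_correlated(self):
        tr = track(1.5 * np.arange(100) * 10.0)
        vac = velocity_autocorrelation([tr], 10)
        assert np.allclose(vac, 1.0)

    def test_normalization_at_zero_lag(self, rng):
        tr = track(*rng.normal(size=(2, 100)))
        assert velocity_autocorrelation([tr], 5)[0] == 1.0

    def test_iid_steps_uncorrelated(self, rng):
        trs = [track(*np.cumsum(rng.normal(0, 1, (300, 2)), axis=0).T)
               for _ in range(30)]
        vac = velocity_autocorrelation(trs, 5)
        n_pairs = 30 * 295
        assert np.all(np.abs(vac[1:]) < 3.0 / math.sqrt(n_pairs))

    def test_zero_velocities_rejected(self):
        with pytest.raises(ValueError):
            velocity_autocorrelation([track(np.zeros(50))], 5)


class TestStraightness:
    def test_straight_line_is_one(self):
        assert track_straightness(track(np.arange(50.0))) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        x = np.concatenate([np.arange(25.0), np.arange(25.0)[::-1]])
        assert track_straightness(track(x)) == pytest.approx(0.0)

    def test_right_angle_path(self):
        x = np.concatenate([np.arange(11.0), np.full(10, 10.0)])
        y = np.concatenate([np.zeros(11), np.arange(1.0, 11.0)])
        assert track_straightness(track(x, y)) == pytest.approx(math.sqrt(2) / 2)

    def test_zero_path_rejected(self):
        with pytest.raises(ValueError):
            track_straightness(track(np.zeros(10)))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_never_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        tr = track(*np.cumsum(rng.normal(size=(20, 2)), axis=0).T)
        assert track_straightness(tr) <= 1.0 + 1e-12


class TestSegmentation:
    def test_constructed_still_jump_still(self):
        x = np.concatenate([np.zeros(11), [500.0] * 10])
        traps, steps = segment_traps_steps(track(x), v_eps=6.0, t_min=30.0)
        assert len(traps) == 2 and len(steps) == 1
        assert steps[0].displacement == pytest.approx(500.0)

    def test_ballistic_is_one_step_no_traps(self):
        tr = track(100.0 * np.arange(50))    # 10 nm/s > v_eps
        traps, steps = segment_traps_steps(tr, v_eps=6.0, t_min=30.0)
        assert traps == [] and len(steps) == 1

    def test_traps_and_steps_partition_the_track(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.choice([0.0, 0.0, 0.0, 200.0], size=120))
        tr = track(x)
        traps, steps = segment_traps_steps(tr, v_eps=6.0, t_min=30.0)
        total = sum(t.duration for t in traps) + sum(s.duration for s in steps)
        assert total == pytest.approx(tr.times[-1] - tr.times[0])

    @pytest.mark.parametrize("v_eps_pair", [(2.0, 6.0), (6.0, 20.0)])
    def test_raising_threshold_never_decreases_trapped_time(self, v_eps_pair):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 40.0, 300))
        tr = track(x)
        lo, hi = v_eps_pair
        t_lo = sum(t.duration for t in segment_traps_steps(tr, lo, 30.0)[0])
        t_hi = sum(t.duration for t in segment_traps_steps(tr, hi, 30.0)[0])
        assert t_hi >= t_lo

    def test_default_threshold_from_metadata(self):
        x = np.concatenate([np.zeros(11), [500.0] * 10])
        traps, steps = segment_traps_steps(track(x))   # V_u=120 in meta
        assert len(traps) == 2 and len(steps) == 1

    def test_nonuniform_spacing_refused(self):
        tr = Trajectory(times=np.array([0.0, 1.0, 3.0, 4.0]),
                        positions=np.zeros((4, 2)))
        with pytest.raises(ValueError, match="resample"):
            segment_traps_steps(tr, v_eps=1.0)


class TestKurtosis:
    def test_two_point_sample(self):
        assert kurtosis([-1, 1] * 10) == pytest.approx(1.0)

    def test_gaussian_reference_is_three(self, rng):
        assert kurtosis(rng.normal(size=100_000)) == pytest.approx(3.0, abs=0.1)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            kurtosis([2.0] * 10)
        with pytest.raises(ValueError):
            kurtosis([1.0, 2.0])    # too few

    def test_ratio_of_identical_distributions_is_one(self, rng):
        a = rng.normal(size=5000)
        r = kurtosis_ratio(a, a)
        assert r.ratio == pytest.approx(1.0)
        assert not r.low_sample_warning

    def test_heavy_tailed_traps_dominate_gaussian_steps(self, rng):
        traps = (1.0 + rng.pareto(1.5, size=5000)) * 10.0
        steps = rng.normal(100.0, 10.0, size=5000)
        assert kurtosis_ratio(traps, steps).ratio > 1.0

    def test_small_samples_flagged(self, rng):
        r = kurtosis_ratio(rng.normal(size=5), rng.normal(size=5000))
        assert r.low_sample_warning
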