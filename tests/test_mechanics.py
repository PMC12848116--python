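"""Per-end physics: Bell kinetics, SLS substrate, Hill motors, coupled step."""

import math

import numpy as np
import pytest

from glassyclutch import (
    Clutch,
    ConstantOffTime,
    EndModule,
    MotorEnsemble,
    OffTimeDistribution,
    SubstrateSLS,
    bell_off_rate,
    clutch_kinetics_step,
    end_step,
    force_relaxation_efolding,
    hill_retrograde,
    substrate_step,
)


def make_end(n_clutches=75, k_c=0.8, r_on=1.0, F_bond=2.0, N_m=50, F_motor=2.0,
             V_u=120.0, k_a=1.0, k_l=1.0, eta=10.0, tau_min=1.0,
             constant=True) -> EndModule:
    off = ConstantOffTime(tau_min) if constant else OffTimeDistribution(1.5, tau_min, 100.0)
    return EndModule.fresh(
        n_clutches, SubstrateSLS(k_a=k_a, k_l=k_l, eta=eta),
        MotorEnsemble(N_m=N_m, F_motor=F_motor, V_u=V_u),
        k_c=k_c, r_on=r_on, F_bond=F_bond, off_dist=off,
    )


class TestBellLaw:
    def test_unloaded_rate_is_reciprocal_tau(self):
        assert bell_off_rate(0.0, 5.0, 2.0) == pytest.approx(0.2)

    def test_force_amplification(self):
        assert bell_off_rate(2.0, 1.0, 2.0) == pytest.approx(math.e)
        assert bell_off_rate(4.0, 2.0, 2.0) == pytest.approx(math.e ** 2 / 2)

    def test_compression_amplifies_like_tension(self):
        assert bell_off_rate(-3.0, 1.0, 2.0) == bell_off_rate(3.0, 1.0, 2.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            bell_off_rate(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            bell_off_rate(1.0, 1.0, -2.0)


class TestHillRelation:
    def test_limits_and_midpoint(self):
        m = MotorEnsemble(N_m=50, F_motor=2.0, V_u=120.0)
        assert hill_retrograde(0.0, m) == 120.0
        assert hill_retrograde(m.F_stall, m) == 0.0
        assert hill_retrograde(m.F_stall / 2, m) == pytest.approx(60.0)
        assert hill_retrograde(2 * m.F_stall, m) == 0.0  # clamped past stall

    def test_no_motors_no_flow(self):
        m = MotorEnsemble(N_m=0, F_motor=2.0, V_u=120.0)
        assert hill_retrograde(0.0, m) == 0.0

    def test_negative_load_rejected(self):
        m = MotorEnsemble(N_m=5, F_motor=2.0, V_u=120.0)
        with pytest.raises(ValueError):
            hill_retrograde(-1.0, m)


class TestClutchKinetics:
    def test_zero_on_rate_never_binds(self, rng):
        c = Clutch()
        for _ in range(1000):
            clutch_kinetics_step(c, 0.0, 0.0, 0.01, 0.0, ConstantOffTime(1.0), rng)
        assert not c.bound

    def test_binding_probability_exponential_survival(self, rng):
        # P(bind) = 1 - exp(-r_on dt) at r_on=1, dt=0.01
        n, hits = 200_000, 0
        for _ in range(n):
            c = Clutch()
            clutch_kinetics_step(c, 1.0, 0.0, 0.01, 0.0, ConstantOffTime(1.0), rng)
            hits += c.bound
        p = -math.expm1(-0.01)
        assert hits / n == pytest.approx(p, abs=3 * math.sqrt(p / n))

    def test_steady_state_occupancy(self, rng):
        # frozen forces, r_on = 1, r_off = 3: bound fraction -> 1/4
        c = Clutch()
        dt, n = 0.01, 100_000
        bound_time = 0
        for _ in range(n):
            clutch_kinetics_step(c, 1.0, 3.0, dt, 0.0, ConstantOffTime(1.0), rng)
            bound_time += c.bound
        assert bound_time / n == pytest.approx(0.25, abs=0.01)

    def test_binding_occurs_at_zero_extension_with_fresh_tau(self, rng):
        c = Clutch()
        d = OffTimeDistribution(1.5, 1.0)
        while not c.bound:
            clutch_kinetics_step(c, 50.0, 0.0, 0.1, 7.5, d, rng)
        assert c.x_c == 7.5
        assert c.tau_off >= 1.0 and math.isfinite(c.tau_off)


class TestSubstrateSLS:
    def test_creep_to_long_term_compliance(self):
        sub = SubstrateSLS(k_a=1.0, k_l=1.0, eta=10.0)
        for _ in range(20000):     # 200 s = 20 tau_s at dt = tau_s/100
            substrate_step(sub, 10.0, 0.1)
        assert sub.x_s == pytest.approx(10.0, rel=1e-3)   # F / k_l

    def test_instantaneous_elastic_response(self):
        sub = SubstrateSLS(k_a=1.0, k_l=1.0, eta=10.0)
        substrate_step(sub, 10.0, 1e-4)
        assert sub.x_s == pytest.approx(10.0 / 2.0, rel=1e-3)  # F/(k_a+k_l)

    @pytest.mark.parametrize("dt_frac, tol", [(0.01, 0.01), (0.001, 0.001)])
    def test_fixed_displacement_relaxation_time(self, dt_frac, tol):
        # force excess decays toward k_l x with e-folding time eta/k_a
        sub = SubstrateSLS(k_a=1.0, k_l=1.0, eta=10.0, x_s=5.0, F_s=20.0)
        tau = force_relaxation_efolding(sub, 5.0, dt_frac * 10.0)
        assert tau == pytest.approx(10.0, rel=tol)

    def test_timestep_bound_enforced(self):
        sub = SubstrateSLS(k_a=1.0, k_l=1.0, eta=10.0)
        with pytest.raises(ValueError, match="tau_s/10"):
            substrate_step(sub, 1.0, 2.0)

    def test_tau_s_property(self):
        assert SubstrateSLS(k_a=2.0, k_l=1.0, eta=30.0).tau_s == 15.0


class TestEndStep:
    def test_unloaded_end_runs_at_free_velocity(self, rng):
        end = make_end(r_on=0.0)
        for i in range(200):
            end_step(end, 0.01, rng, i)
        assert end.substrate.F_s == 0.0
        assert end.V_r == 120.0
        assert end.n_bound == 0

    def test_no_motors_no_loading(self, rng):
        end = make_end(N_m=0)
        for _ in range(500):
            end_step(end, 0.01, rng)
        assert end.V_r == 0.0
        x_s = end.substrate.x_s
        for c in end.clutches:      # extensions never grow without motor pull
            assert abs(c.x_c - x_s) < 1e-9

    def test_force_bookkeeping_invariant(self, rng):
        end = make_end(constant=False, eta=100.0)
        for _ in range(2000):
            end_step(end, 0.01, rng)
            expect = end.total_clutch_force()
            assert abs(end.substrate.F_s - expect) < 1e-9 * max(1.0, abs(expect))

    def test_retrograde_flow_always_within_bounds(self, rng):
        end = make_end(constant=False)
        for _ in range(2000):
            end_step(end, 0.01, rng)
            assert 0.0 <= end.V_r <= end.motors.V_u

    def test_single_clutch_load_and_stall_matches_ode(self, rng):
        # One permanently bound clutch, rigid substrate: the load follows
        # dF/dt = k_c V_u (1 - F/F_stall), so F(t) = F_stall(1 - exp(-t/t0))
        # with t0 = F_stall/(k_c V_u), and V_r falls monotonically to stall.
        end = make_end(n_clutches=1, r_on=0.0, F_bond=1e9, N_m=5, F_motor=2.0,
                       k_c=0.8, V_u=120.0, k_a=1e3, k_l=1e3, eta=1e12)
        end.clutches[0].bound = True
        end.clutches[0].tau_off = 1e12
        dt, n = 0.001, 2000
        v_prev = np.inf
        for i in range(1, n + 1):
            end_step(end, dt, rng)
            assert end.V_r <= v_prev + 1e-9
            v_prev = end.V_r
        F_stall = 10.0
        t0 = F_stall / (0.8 * 120.0)
        expected = F_stall * (1.0 - math.exp(-n * dt / t0))
        assert end.substrate.F_s == pytest.approx(expected, rel=0.02)

    def test_load_and_fail_cycling_on_stiff_elastic_substrate(self, rng):
        # constant tau_off on an effectively elastic substrate (window << tau_s):
        # the ensemble must show recurring force buildup and collapse.
        end = make_end(constant=True, tau_min=1.0, k_a=1.0, k_l=1.0, eta=1e6)
        dt, T = 0.02, 600.0
        F = np.empty(int(T / dt))
        for i in range(F.size):
            end_step(end, dt, rng)
            F[i] = end.substrate.F_s
        peak = np.max(F)
        assert peak > 20.0
        # count collapses: drops below 25% of peak after having exceeded 75%
        hi, lo = 0.75 * peak, 0.25 * peak
        collapses, armed = 0, False
        for f in F:
            if f > hi:
                armed = True
            elif f < lo and armed:
                collapses += 1
                armed = False
        assert collapses >= 3      # >= 5 collapses per 1000 s

    def test_nan_state_raises_with_step_index(self, rng):
        end = make_end()
        end.substrate.F_s = float("nan")
        from glassyclutch.mechanics import IntegrationError
        with pytest.raises(IntegrationError, match="step 42"):
            end_step(end, 0.01, rng, step_index=42)
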