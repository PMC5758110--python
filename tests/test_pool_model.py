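"""Three-pool model: steady state, exact propagation, propensity calculus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primekin.pool_model import (
    DegenerateSteadyStateError,
    PoolModelParams,
    PoolState,
    PrimingPropensities,
    ResolutionError,
    Topology,
    hill_scale,
    priming_propensities,
    propensity_ratio,
    simulate_time_course,
    slowest_relaxation_time,
    steady_state_pools,
)

rates = st.floats(min_value=0.01, max_value=0.5)


class TestSteadyState:
    def test_closed_form_example(self):
        params = PoolModelParams(depot=1000, k1=0.01, k_minus1=0.05, k2=0.1,
                                 k_minus2=0.05, gamma_fast=50.0)
        ss = steady_state_pools(params)
        assert ss.srp == pytest.approx(200.0)
        assert ss.rrp == pytest.approx(400.0)
        assert ss.fused == 0.0
        assert ss.depot == 1000.0

    def test_no_forward_flux_empties_rrp(self):
        params = PoolModelParams(depot=800, k1=0.03, k_minus1=0.06, k2=0.0,
                                 k_minus2=0.04, gamma_fast=50.0)
        ss = steady_state_pools(params)
        assert ss.rrp == 0.0
        assert ss.srp == pytest.approx(0.03 * 800 / 0.06)

    def test_zero_unpriming_is_degenerate(self):
        params = PoolModelParams(depot=800, k1=0.03, k_minus1=0.0, k2=0.1,
                                 k_minus2=0.04, gamma_fast=50.0)
        with pytest.raises(DegenerateSteadyStateError):
            steady_state_pools(params)

    @given(depot=st.floats(100, 2000), k1=rates, km1=rates, k2=rates, km2=rates)
    def test_matches_long_time_integration(self, depot, k1, km1, k2, km2):
        """Resting pools agree with the ODE's long-time limit within 0.1%."""
        params = PoolModelParams(depot=depot, k1=k1, k_minus1=km1, k2=k2,
                                 k_minus2=km2, gamma_fast=50.0)
        horizon = 25.0 * slowest_relaxation_time(params)
        traj = simulate_time_course(
            params, PoolState(depot=depot, srp=0, rrp=0),
            stimulus_time=horizon * 0.999, duration=horizon, dt=horizon / 100,
            check_resolution=False,
        )
        # last pre-stimulus sample
        idx = int(np.searchsorted(traj.times, horizon * 0.999)) - 1
        ss = steady_state_pools(params)
        assert traj.srp[idx] == pytest.approx(ss.srp, rel=1e-3)
        assert traj.rrp[idx] == pytest.approx(ss.rrp, rel=1e-3)


class TestSimulation:
    def test_parallel_no_repriming_matches_two_exponentials(self):
        """Decoupled draining pools follow the closed two-exponential form."""
        params = PoolModelParams(depot=0, k1=0, k_minus1=0.05, k2=0, k_minus2=0.05,
                                 gamma_fast=50.0, gamma_slow=6.67)
        init = PoolState(depot=0, srp=150, rrp=150)
        traj = simulate_time_course(params, init, stimulus_time=0.0, duration=1.0,
                                    dt=0.001, repriming_after_flash=False)
        t = traj.times
        closed = 150 * (1 - np.exp(-50 * t)) + 150 * (1 - np.exp(-6.67 * t))
        assert np.max(np.abs(traj.capacitance - closed)) < 0.01

    def test_empty_pools_stay_flat(self):
        params = PoolModelParams(depot=0, k1=0.01, k_minus1=0.05, k2=0.1,
                                 k_minus2=0.05, gamma_fast=50.0, gamma_slow=5.0)
        init = PoolState(depot=0, srp=0, rrp=0)
        traj = simulate_time_course(params, init, 0.1, 1.0, 0.001)
        assert np.allclose(traj.capacitance, 0.0, atol=1e-12)

    def test_late_time_slope_matches_analytic_asymptote(self):
        """With repriming on, sustained fusion settles at the linear system's
        asymptotic flux J - k_-1*SRP* (which is J itself when post-flash
        unpriming back to the depot is negligible)."""
        params = PoolModelParams(depot=1000, k1=0.04, k_minus1=0.5, k2=0.5,
                                 k_minus2=0.5, gamma_fast=50.0, gamma_slow=10.0)
        init = steady_state_pools(params)
        traj = simulate_time_course(params, init, stimulus_time=0.0, duration=30.0,
                                    dt=0.002, repriming_after_flash=True)
        mask = traj.times > 25.0
        slope = np.polyfit(traj.times[mask], traj.capacitance[mask], 1)[0]
        # closed-form post-flash stationary pools of the 2x2 affine system
        j = params.influx
        km1, k2, km2 = params.k_minus1, params.k2, params.k_minus2
        gf, gs = params.gamma_fast, params.gamma_slow
        srp_star = j / (km1 + k2 + gs - km2 * k2 / (km2 + gf))
        assert slope == pytest.approx(j - km1 * srp_star, rel=1e-6)
        # with negligible post-flash unpriming the slope is the influx itself
        params2 = PoolModelParams(depot=1000, k1=0.04, k_minus1=0.001, k2=0.5,
                                  k_minus2=0.5, gamma_fast=50.0, gamma_slow=10.0)
        traj2 = simulate_time_course(
            params2, PoolState(depot=1000, srp=40, rrp=40), stimulus_time=0.0,
            duration=30.0, dt=0.002, repriming_after_flash=True)
        mask2 = traj2.times > 25.0
        slope2 = np.polyfit(traj2.times[mask2], traj2.capacitance[mask2], 1)[0]
        assert slope2 == pytest.approx(params2.influx, rel=1e-3)

    def test_mass_conserved_with_finite_depot(self):
        params = PoolModelParams(depot=500, k1=0.05, k_minus1=0.05, k2=0.2,
                                 k_minus2=0.1, gamma_fast=40.0, gamma_slow=8.0,
                                 finite_depot=True)
        init = PoolState(depot=500, srp=120, rrp=80)
        traj = simulate_time_course(params, init, 0.5, 3.0, 0.002)
        total = traj.depot + traj.srp + traj.rrp + traj.fused
        assert np.allclose(total, init.total, rtol=1e-10)

    @given(
        srp=st.floats(0, 300), rrp=st.floats(0, 300),
        topology=st.sampled_from(list(Topology)),
        repriming=st.booleans(),
    )
    def test_capacitance_is_monotone(self, srp, rrp, topology, repriming):
        params = PoolModelParams(depot=500, k1=0.02, k_minus1=0.05, k2=0.1,
                                 k_minus2=0.05, gamma_fast=40.0, gamma_slow=8.0,
                                 topology=topology)
        init = PoolState(depot=500, srp=srp, rrp=rrp)
        traj = simulate_time_course(params, init, 0.2, 2.0, 0.002,
                                    repriming_after_flash=repriming)
        assert np.all(np.diff(traj.capacitance) >= -1e-9)

    def test_sequential_drains_srp_through_rrp(self):
        """In the sequential topology SRP empties via maturation, not direct fusion."""
        params = PoolModelParams(depot=0, k1=0, k_minus1=0.05, k2=3.0, k_minus2=0.05,
                                 gamma_fast=50.0, gamma_slow=0.0,
                                 topology=Topology.SEQUENTIAL)
        init = PoolState(depot=0, srp=150, rrp=150)
        traj = simulate_time_course(params, init, 0.0, 5.0, 0.001,
                                    repriming_after_flash=False)
        assert traj.srp[-1] < 1e-3
        assert traj.capacitance[-1] == pytest.approx(300.0, rel=1e-6)

    def test_coarse_dt_raises_unless_disabled(self):
        params = PoolModelParams(depot=100, k1=0.01, k_minus1=0.05, k2=0.1,
                                 k_minus2=0.05, gamma_fast=50.0)
        init = PoolState(depot=100, srp=10, rrp=10)
        with pytest.raises(ResolutionError):
            simulate_time_course(params, init, 0.1, 1.0, dt=0.1)
        traj = simulate_time_course(params, init, 0.1, 1.0, dt=0.1,
                                    check_resolution=False)
        assert len(traj.times) == 11

    def test_invalid_inputs_rejected(self):
        params = PoolModelParams(depot=100, k1=0.01, k_minus1=0.05, k2=0.1,
                                 k_minus2=0.05, gamma_fast=50.0)
        init = PoolState(depot=100, srp=10, rrp=10)
        with pytest.raises(ValueError):
            simulate_time_course(params, init, 2.0, 1.0, 0.001)
        with pytest.raises(ValueError):
            simulate_time_course(params, init, 0.1, 1.0, -0.001)
        with pytest.raises(ValueError):
            PoolModelParams(depot=-1, k1=0.01, k_minus1=0.05, k2=0.1,
                            k_minus2=0.05, gamma_fast=50.0)


class TestPropensities:
    def test_direct_formula(self):
        p = priming_propensities(srp0=200.0, rrp0=400.0)
        assert p.p1 == pytest.approx(200.0)
        assert p.p2 == pytest.approx(2.0)

    def test_equal_pools_give_unit_p2(self):
        assert priming_propensities(300.0, 300.0).p2 == pytest.approx(1.0)

    def test_zero_srp_with_rrp_is_undefined(self):
        with pytest.raises(ValueError):
            priming_propensities(0.0, 10.0)

    def test_ratio_examples(self):
        a = PrimingPropensities(200.0, 2.0)
        b = PrimingPropensities(100.0, 4.0)
        assert propensity_ratio(a, b) == pytest.approx((2.0, 0.5))
        assert propensity_ratio(a, a) == pytest.approx((1.0, 1.0))

    def test_ratio_rejects_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            propensity_ratio(PrimingPropensities(1.0, 1.0), PrimingPropensities(0.0, 1.0))

    @given(scale=st.floats(0.1, 10.0), k1=rates, km1=rates, k2=rates, km2=rates)
    def test_time_rescaling_invariance(self, scale, k1, km1, k2, km2):
        """p1 and p2 depend only on rate ratios, so rescaling time leaves them fixed."""
        a = PoolModelParams(depot=1000, k1=k1, k_minus1=km1, k2=k2, k_minus2=km2,
                            gamma_fast=50.0)
        b = PoolModelParams(depot=1000, k1=k1 * scale, k_minus1=km1 * scale,
                            k2=k2 * scale, k_minus2=km2 * scale, gamma_fast=50.0)
        pa, pb = (steady_state_pools(x) for x in (a, b))
        prop_a = priming_propensities(pa.srp, pa.rrp)
        prop_b = priming_propensities(pb.srp, pb.rrp)
        assert prop_a.p1 == pytest.approx(prop_b.p1, rel=1e-9)
        assert prop_a.p2 == pytest.approx(prop_b.p2, rel=1e-9)


def test_hill_hook_is_saturating_and_monotone():
    values = [hill_scale(ca, ec50_nm=200.0, h=2.0) for ca in (0, 50, 200, 1000, 1e6)]
    assert values[0] == 0.0
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[2] == pytest.approx(0.5)
    assert values[-1] < 1.0
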