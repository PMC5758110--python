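"""Burst-window measures, triple-exponential decomposition, IRP/RRP staircase."""

import numpy as np
import pytest

from primekin.kinetics_fit import (
    DegenerateFitError,
    decomposition_to_pools,
    fit_triple_exponential,
    measure_bursts,
    measure_irp_rrp,
)
from primekin.synthetic_data import (
    FlashProtocol,
    GroundTruth,
    NoiseModel,
    default_depolarization_protocol,
    synth_capacitance_trace,
    synth_depolarization_recording,
)


def expected_bursts(truth: GroundTruth):
    """Closed-form window measures of the generative model (the oracle)."""
    cm = lambda t: (
        truth.a_fast * (1 - np.exp(-t / truth.tau_fast))
        + truth.a_slow * (1 - np.exp(-t / truth.tau_slow))
        + truth.sustained_rate * t
    )
    burst = cm(0.5)
    total = cm(5.0)
    return burst, (total - burst) / 4.5, total


class TestMeasureBursts:
    def test_closed_form_values(self, reference_truth, flash_protocol):
        trace = synth_capacitance_trace(reference_truth, flash_protocol)
        m = measure_bursts(trace)
        burst, rate, total = expected_bursts(reference_truth)
        assert burst == pytest.approx(314.6, abs=0.1)  # frozen from the oracle
        assert rate == pytest.approx(41.2, abs=0.1)
        assert m.burst_05s == pytest.approx(burst, abs=0.5)
        assert m.sustained_rate_win == pytest.approx(rate, abs=0.1)
        assert m.total_5s == pytest.approx(total, abs=0.5)

    def test_flat_trace_measures_zero(self, flash_protocol):
        truth = GroundTruth(0.0, 0.02, 0.0, 0.15, 0.0)
        trace = synth_capacitance_trace(truth, flash_protocol)
        m = measure_bursts(trace)
        assert m.burst_05s == 0.0
        assert m.sustained_rate_win == 0.0
        assert m.total_5s == 0.0

    def test_short_trace_rejected(self, reference_truth):
        proto = FlashProtocol(flash_time=0.5, duration=3.0)
        trace = synth_capacitance_trace(reference_truth, proto)
        with pytest.raises(ValueError):
            measure_bursts(trace)

    def test_estimator_is_unbiased_under_noise(self, reference_truth, flash_protocol):
        """Window estimates average to the truth within 1 fF across seeds."""
        burst_true, rate_true, _ = expected_bursts(reference_truth)
        bursts = []
        for seed in range(200):
            trace = synth_capacitance_trace(
                reference_truth, flash_protocol, NoiseModel(sigma=5.0, seed=seed)
            )
            bursts.append(measure_bursts(trace).burst_05s)
        assert abs(np.mean(bursts) - burst_true) < 1.0


class TestTripleExponentialFit:
    def test_noiseless_recovery(self, reference_truth, flash_protocol):
        trace = synth_capacitance_trace(reference_truth, flash_protocol)
        d = fit_triple_exponential(trace)
        assert d.converged and not d.degenerate
        assert d.a_fast == pytest.approx(150.0, rel=1e-3)
        assert d.tau_fast == pytest.approx(0.020, rel=1e-3)
        assert d.a_slow == pytest.approx(150.0, rel=1e-3)
        assert d.tau_slow == pytest.approx(0.150, rel=1e-3)
        assert d.sustained_rate == pytest.approx(40.0, rel=1e-3)

    def test_pure_ramp_has_no_bursts(self, flash_protocol):
        truth = GroundTruth(0.0, 0.02, 0.0, 0.15, 40.0)
        trace = synth_capacitance_trace(truth, flash_protocol)
        d = fit_triple_exponential(trace)
        assert d.a_fast < 1.0 and d.a_slow < 1.0
        assert d.sustained_rate == pytest.approx(40.0, rel=1e-3)

    def test_exponential_sustained_mode(self, flash_protocol):
        """A tau=3 s sustained component is still reported as its mean linear rate."""
        truth = GroundTruth(150.0, 0.020, 150.0, 0.150, sustained_rate=40.0)
        trace = synth_capacitance_trace(truth, flash_protocol, sustained_tau=3.0)
        d = fit_triple_exponential(trace, sustained="exponential")
        assert d.converged
        assert d.a_fast == pytest.approx(150.0, rel=0.05)
        # mean linear rate of 40*3*(1-exp(-t/3))/t over 5 s
        expected_rate = 40.0 * 3.0 * (1 - np.exp(-5.0 / 3.0)) / 5.0
        assert d.sustained_rate == pytest.approx(expected_rate, rel=0.05)

    def test_merged_components_flagged_degenerate(self, flash_protocol):
        """A single-burst response cannot support two distinct time constants."""
        t = np.arange(0, 6.0 + 1e-9, 0.001)
        tp = np.maximum(t - 0.5, 0.0)
        values = 300.0 * (1 - np.exp(-tp / 0.048)) + 40.0 * tp
        from primekin.synthetic_data import CapacitanceTrace

        trace = CapacitanceTrace(t, values, flash_protocol, 1000.0)
        d = fit_triple_exponential(trace)
        if d.degenerate:
            assert d.a_fast == 0.0
            assert d.a_slow == pytest.approx(300.0, rel=0.05)
            with pytest.raises(DegenerateFitError):
                decomposition_to_pools(d)
        else:
            # if the optimizer resolves it, both components sit at the shared tau
            assert d.a_fast + d.a_slow == pytest.approx(300.0, rel=0.05)

    def test_noisy_recovery_medians(self, reference_truth, flash_protocol):
        """At 5 fF noise, median recovery errors stay below 10% (amplitudes)
        and 20% (time constants) over seeded replicates."""
        errs = {"a_fast": [], "a_slow": [], "tau_fast": [], "tau_slow": []}
        for seed in range(40):
            trace = synth_capacitance_trace(
                reference_truth, flash_protocol, NoiseModel(sigma=5.0, seed=1000 + seed)
            )
            d = fit_triple_exponential(trace)
            errs["a_fast"].append(abs(d.a_fast - 150) / 150)
            errs["a_slow"].append(abs(d.a_slow - 150) / 150)
            errs["tau_fast"].append(abs(d.tau_fast - 0.020) / 0.020)
            errs["tau_slow"].append(abs(d.tau_slow - 0.150) / 0.150)
        assert np.median(errs["a_fast"]) < 0.10
        assert np.median(errs["a_slow"]) < 0.10
        assert np.median(errs["tau_fast"]) < 0.20
        assert np.median(errs["tau_slow"]) < 0.20

    def test_fit_window_consistency(self, reference_truth, flash_protocol):
        """The fitted model at 5 s reproduces the measured total, and the sum of
        burst amplitudes is never below the window burst minus the sustained
        contribution (the window measure undercounts slow tails)."""
        trace = synth_capacitance_trace(reference_truth, flash_protocol)
        d = fit_triple_exponential(trace)
        m = measure_bursts(trace)
        model_5s = float(d.evaluate(np.array([5.0]))[0])
        assert abs(model_5s - m.total_5s) <= max(3 * d.residual_rms, 1e-6)
        assert d.a_fast + d.a_slow >= m.burst_05s - d.sustained_rate * 0.5 - 1e-6


class TestPoolsFromDecomposition:
    def test_mapping(self, reference_truth, flash_protocol):
        trace = synth_capacitance_trace(reference_truth, flash_protocol)
        d = fit_triple_exponential(trace)
        srp0, rrp0 = decomposition_to_pools(d)
        assert srp0 == pytest.approx(d.a_slow)
        assert rrp0 == pytest.approx(d.a_fast)

    def test_round_trip_through_propensities(self, flash_protocol):
        from primekin.pool_model import priming_propensities

        truth = GroundTruth(a_fast=300.0, tau_fast=0.02, a_slow=150.0,
                            tau_slow=0.15, sustained_rate=30.0)
        trace = synth_capacitance_trace(truth, flash_protocol)
        srp0, rrp0 = decomposition_to_pools(fit_triple_exponential(trace))
        p = priming_propensities(srp0, rrp0)
        assert p.p1 == pytest.approx(150.0, rel=0.01)
        assert p.p2 == pytest.approx(2.0, rel=0.01)


class TestIrpRrp:
    def test_staircase_recovery(self):
        trace = synth_depolarization_recording((40.0, 160.0))
        irp, rrp = measure_irp_rrp(trace)
        assert irp == pytest.approx(40.0, abs=1e-9)
        assert rrp == pytest.approx(160.0, abs=1e-9)

    def test_zero_release(self):
        trace = synth_depolarization_recording((0.0, 0.0))
        assert measure_irp_rrp(trace) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_noisy_recovery(self):
        irps, rrps = [], []
        for seed in range(100):
            trace = synth_depolarization_recording(
                (40.0, 160.0), noise=NoiseModel(sigma=2.0, seed=seed)
            )
            irp, rrp = measure_irp_rrp(trace)
            irps.append(irp)
            rrps.append(rrp)
        assert abs(np.mean(irps) - 40.0) < 3 * 2.0
        assert abs(np.mean(rrps) - 160.0) < 3 * 2.0

    def test_wrong_protocol_rejected(self, reference_truth, flash_protocol):
        trace = synth_capacitance_trace(reference_truth, flash_protocol)
        with pytest.raises(ValueError):
            measure_irp_rrp(trace)
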