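"""Conditioning and integration of carbon-fiber amperometry recordings.

Amperometric currents report catecholamine oxidation at the fiber tip.
Because released transmitter diffuses to the fiber, the current is a
delayed, smeared image of fusion; its running time-integral (the charge)
nevertheless tracks the same cumulative quantity as the capacitance
trace, up to a cell- and geometry-dependent scale factor.  Acquisition
follows the standard chain: 7-pole Bessel low-pass at 1 kHz, sampling at
11.5 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "AmperometryTrace",
    "AgreementResult",
    "bessel_lowpass",
    "subtract_baseline",
    "integrate_charge",
    "charge_capacitance_agreement",
]

DEFAULT_SAMPLING_HZ = 11_500.0
DEFAULT_BESSEL_ORDER = 7
DEFAULT_CUTOFF_HZ = 1_000.0


@dataclass(frozen=True)
class AmperometryTrace:
    """Uniformly sampled amperometric current (pA vs. s)."""

    times: np.ndarray
    current: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_HZ

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.ndim != 1 or t.shape != i.shape or len(t) < 2:
            raise ValueError("times and current must be matching 1-D arrays")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("amperometry trace must be uniformly sampled")
        if not np.all(np.isfinite(i)):
            raise ValueError("current contains non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", i)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class AgreementResult:
    """Least-squares scale and shape discrepancy between charge and capacitance."""

    scale: float  # pC per fF
    discrepancy: float  # RMS of residual, normalised to max charge


def bessel_lowpass(
    trace: AmperometryTrace,
    order: int = DEFAULT_BESSEL_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
) -> AmperometryTrace:
    """Low-pass the current with a digital Bessel filter (unity DC gain).

    The analog prototype is discretised by the bilinear transform with
    frequency prewarping (scipy's default); initial conditions are set to
    the steady state of the first sample, so a constant input passes
    through unchanged.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = signal.bessel(order, cutoff, btype="low", output="sos", fs=trace.sampling_rate)
    zi = signal.sosfilt_zi(sos) * trace.current[0]
    filtered, _ = signal.sosfilt(sos, trace.current, zi=zi)
    return AmperometryTrace(trace.times, filtered, trace.sampling_rate)


def subtract_baseline(trace: AmperometryTrace, window: float = 0.5) -> AmperometryTrace:
    """Subtract the median current of the first ``window`` seconds."""
    if window <= 0:
        raise ValueError("window must be > 0")
    mask = trace.times <= trace.times[0] + window
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(np.median(trace.current[mask]))
    return AmperometryTrace(trace.times, trace.current - baseline, trace.sampling_rate)


def integrate_charge(trace: AmperometryTrace) -> np.ndarray:
    """Cumulative trapezoidal time-integral of the current, in pC.

    pA x s = pC, so no unit factor is needed.  The result is
    non-decreasing whenever the (baseline-subtracted) current is >= 0.
    """
    charge = np.concatenate(
        [[0.0], np.cumsum(np.diff(trace.times) * 0.5 * (trace.current[1:] + trace.current[:-1]))]
    )
    return charge


def charge_capacitance_agreement(
    times: np.ndarray,
    charge_pc: np.ndarray,
    cap_times: np.ndarray,
    cap_values: np.ndarray,
) -> AgreementResult:
    """How well the amperometric charge retraces the capacitance increase.

    Finds the least-squares scale alpha mapping the capacitance change
    onto the charge over the overlapping time range, and reports the RMS
    of the residual normalised to the maximum charge.  Both inputs are
    referenced to their value at the start of the overlap.
    """
    times = np.asarray(times, float)
    charge_pc = np.asarray(charge_pc, float)
    cap_times = np.asarray(cap_times, float)
    cap_values = np.asarray(cap_values, float)
    lo = max(times[0], cap_times[0])
    hi = min(times[-1], cap_times[-1])
    if hi <= lo:
        raise ValueError("charge and capacitance do not overlap in time")
    mask = (times >= lo) & (times <= hi)
    t = times[mask]
    q = charge_pc[mask] - np.interp(lo, times, charge_pc)
    dcm = np.interp(t, cap_times, cap_values) - np.interp(lo, cap_times, cap_values)
    q_span = float(np.max(np.abs(q)))
    c_span = float(np.max(np.abs(dcm)))
    if q_span == 0 or c_span == 0:
        raise ValueError("flat charge or capacitance input: scale is undefined")
    alpha = float(np.dot(dcm, q) / np.dot(dcm, dcm))
    resid = q - alpha * dcm
    discrepancy = float(math.sqrt(np.mean(resid**2)) / q_span)
    return AgreementResult(scale=alpha, discrepancy=discrepancy)
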