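"""Seeded generators of synthetic secretion recordings with known ground truth.

The study's raw electrophysiology is not deposited, so every analysis
here is exercised on generated data that mimics the measured signals:

* flash-photolysis capacitance responses — fast exponential burst
  (tau ~ 10-30 ms), slow burst (tau ~ 70-300 ms) and a near-linear
  sustained phase, plus Gaussian instrument noise;
* amperometric currents — the derivative of fusion, delayed by a
  diffusional kernel, Bessel-filtered at 1 kHz and sampled at 11.5 kHz;
* a dual-dye ratiometric calcium step (pre-flash level, post-flash
  plateau with optional relaxation);
* the 6 x 10 ms + 4 x 100 ms depolarization-train protocol that reads
  out the IRP and RRP as a capacitance staircase.

All randomness flows through an explicit integer seed, so identical
parameters give bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .amperometry import AmperometryTrace, bessel_lowpass

__all__ = [
    "FlashProtocol",
    "DepolarizationProtocol",
    "GroundTruth",
    "NoiseModel",
    "CapacitanceTrace",
    "CalciumSeries",
    "synth_capacitance_trace",
    "synth_calcium_step",
    "synth_amperometry_trace",
    "synth_depolarization_recording",
    "default_depolarization_protocol",
]

DEFAULT_CAP_SAMPLING_HZ = 1_000.0
AMPEROMETRY_SAMPLING_HZ = 11_500.0


@dataclass(frozen=True)
class FlashProtocol:
    """Calcium-uncaging stimulus: an instantaneous [Ca2+] step at flash_time.

    pre_ca is the basal calcium level (nM), post_ca the post-flash level
    (uM); the flash itself (1-2 ms of UV light in the experiment) is
    treated as instantaneous.
    """

    flash_time: float  # s
    pre_ca: float = 500.0  # nM
    post_ca: float = 20.0  # uM
    duration: float = 6.0  # s

    def __post_init__(self) -> None:
        if not 0 <= self.flash_time < self.duration:
            raise ValueError("require 0 <= flash_time < duration")
        if self.post_ca * 1000.0 <= self.pre_ca:
            raise ValueError("post-flash calcium must exceed the basal level")


def default_depolarization_protocol(
    first_pulse: float = 0.5, gap: float = 0.1
) -> "DepolarizationProtocol":
    """The standard 6 x 10 ms + 4 x 100 ms train, -70 -> +20 mV.

    Inter-pulse gap defaults to 100 ms (not reported in the source
    protocol; wide enough to measure pre/post-pulse baselines).
    """
    durations = [0.010] * 6 + [0.100] * 4
    starts = []
    t = first_pulse
    for d in durations:
        starts.append(t)
        t += d + gap
    return DepolarizationProtocol(
        pulse_starts=tuple(starts), pulse_durations=tuple(durations)
    )


@dataclass(frozen=True)
class DepolarizationProtocol:
    """Train of voltage-clamp depolarizations (brief pulses probe the IRP,
    long pulses deplete the remaining RRP)."""

    pulse_starts: tuple[float, ...]
    pulse_durations: tuple[float, ...]
    v_rest: float = -70.0  # mV
    v_pulse: float = 20.0  # mV

    def __post_init__(self) -> None:
        starts = tuple(float(s) for s in self.pulse_starts)
        durs = tuple(float(d) for d in self.pulse_durations)
        if len(starts) != len(durs) or not starts:
            raise ValueError("pulse_starts and pulse_durations must match and be non-empty")
        if any(d <= 0 for d in durs):
            raise ValueError("pulse durations must be > 0")
        ends = [s + d for s, d in zip(starts, durs)]
        for i in range(1, len(starts)):
            if starts[i] <= ends[i - 1]:
                raise ValueError("pulses must be ordered and non-overlapping")
        object.__setattr__(self, "pulse_starts", starts)
        object.__setattr__(self, "pulse_durations", durs)

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_starts)

    @property
    def pulse_ends(self) -> tuple[float, ...]:
        return tuple(s + d for s, d in zip(self.pulse_starts, self.pulse_durations))


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters of a flash response.

    The capacitance response is a_fast*(1-exp(-t'/tau_fast)) +
    a_slow*(1-exp(-t'/tau_slow)) + sustained_rate*t' for post-flash time
    t'.  a_fast corresponds to the RRP, a_slow to the SRP.
    """

    a_fast: float  # fF
    tau_fast: float  # s
    a_slow: float  # fF
    tau_slow: float  # s
    sustained_rate: float  # fF/s

    def __post_init__(self) -> None:
        if self.a_fast < 0 or self.a_slow < 0 or self.sustained_rate < 0:
            raise ValueError("amplitudes and sustained rate must be >= 0")
        if not 0 < self.tau_fast < self.tau_slow:
            raise ValueError("require 0 < tau_fast < tau_slow")

    def evaluate(self, t_post: np.ndarray, sustained_tau: float | None = None) -> np.ndarray:
        """Noiseless response at post-flash times (clipped at 0 before flash).

        With ``sustained_tau`` the third component is an exponential
        A(1-exp(-t/tau)) of the same initial rate instead of a ramp.
        """
        tp = np.maximum(np.asarray(t_post, dtype=float), 0.0)
        out = self.a_fast * -np.expm1(-tp / self.tau_fast)
        out += self.a_slow * -np.expm1(-tp / self.tau_slow)
        if sustained_tau is None:
            out += self.sustained_rate * tp
        else:
            if sustained_tau < 1.0:
                raise ValueError("sustained_tau must be >= 1 s")
            out += self.sustained_rate * sustained_tau * -np.expm1(-tp / sustained_tau)
        return out


@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. Gaussian instrument noise with an optional linear drift.

    sigma is in the units of the carrier signal (fF for capacitance, pA
    for current).  A seed is mandatory whenever sigma > 0 or drift != 0.
    """

    sigma: float = 0.0
    seed: int | None = None
    drift_rate: float = 0.0  # signal units per second

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")

    def apply(self, times: np.ndarray, values: np.ndarray) -> np.ndarray:
        out = values + self.drift_rate * (times - times[0])
        if self.sigma > 0:
            rng = np.random.default_rng(self.seed)
            out = out + rng.normal(0.0, self.sigma, size=len(values))
        return out


@dataclass(frozen=True)
class CapacitanceTrace:
    """Uniformly sampled membrane-capacitance recording (fF vs. s) with its
    stimulus protocol; generated traces carry their ground truth."""

    times: np.ndarray
    values: np.ndarray
    protocol: FlashProtocol | DepolarizationProtocol
    sampling_rate: float
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or len(t) < 2:
            raise ValueError("times and values must be matching 1-D arrays")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("capacitance trace must be uniformly sampled")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class CalciumSeries:
    """Intracellular [Ca2+] time course in nM (ratio-trace compatible)."""

    times: np.ndarray
    ca_nm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.ca_nm, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and ca_nm must be matching 1-D arrays")
        if np.any(c < 0):
            raise ValueError("calcium concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ca_nm", c)


def synth_capacitance_trace(
    truth: GroundTruth,
    protocol: FlashProtocol,
    noise: NoiseModel = NoiseModel(),
    sampling_rate: float = DEFAULT_CAP_SAMPLING_HZ,
    sustained_tau: float | None = None,
) -> CapacitanceTrace:
    """Generate a flash-response capacitance trace.

    Zero before the flash, then the two-burst-plus-sustained waveform of
    ``truth``, plus Gaussian noise.  The sampling rate must resolve the
    fast burst (>= 10 / tau_fast).
    """
    if sampling_rate < 10.0 / truth.tau_fast:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz cannot resolve tau_fast={truth.tau_fast}s "
            f"(need >= {10.0 / truth.tau_fast:.0f} Hz)"
        )
    n = int(round(protocol.duration * sampling_rate))
    times = np.arange(n + 1) / sampling_rate
    values = truth.evaluate(times - protocol.flash_time, sustained_tau=sustained_tau)
    values = noise.apply(times, values)
    return CapacitanceTrace(times, values, protocol, sampling_rate, ground_truth=truth)


def synth_calcium_step(
    protocol: FlashProtocol,
    decay_tau: float = math.inf,
    plateau_nm: float | None = None,
    sampling_rate: float = DEFAULT_CAP_SAMPLING_HZ,
) -> CalciumSeries:
    """Calcium time course: basal level, instantaneous step at the flash,
    optional exponential relaxation toward a plateau."""
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0 (use inf for no decay)")
    n = int(round(protocol.duration * sampling_rate))
    times = np.arange(n + 1) / sampling_rate
    post_nm = protocol.post_ca * 1000.0
    ca = np.full(n + 1, protocol.pre_ca)
    after = times >= protocol.flash_time
    if math.isinf(decay_tau):
        ca[after] = post_nm
    else:
        target = post_nm if plateau_nm is None else plateau_nm
        tp = times[after] - protocol.flash_time
        ca[after] = target + (post_nm - target) * np.exp(-tp / decay_tau)
    return CalciumSeries(times, ca)


def synth_amperometry_trace(
    cap: CapacitanceTrace,
    charge_per_ff: float = 0.002,  # pC of oxidation charge per fF fused
    diffusion_tau: float = 0.05,  # s
    noise: NoiseModel = NoiseModel(),
    sampling_rate: float = AMPEROMETRY_SAMPLING_HZ,
    bessel_cutoff: float = 1_000.0,
) -> AmperometryTrace:
    """Amperometric current implied by a (noiseless) capacitance trace.

    current = charge_per_ff * dCm/dt, convolved with a causal unit-area
    exponential kernel (the diffusional delay to the fiber), resampled to
    11.5 kHz and Bessel-filtered at 1 kHz.  The unit-area kernel and the
    unity-DC-gain filter preserve the total integrated charge.
    """
    if diffusion_tau < 0:
        raise ValueError("diffusion_tau must be >= 0")
    dt = 1.0 / sampling_rate
    n = int(round((cap.times[-1] - cap.times[0]) / dt))
    times = cap.times[0] + np.arange(n + 1) * dt
    cm = np.interp(times, cap.times, cap.values)
    current = charge_per_ff * np.gradient(cm, dt)
    if diffusion_tau > 0:
        klen = max(int(round(10.0 * diffusion_tau / dt)), 2)
        kernel = np.exp(-np.arange(klen) * dt / diffusion_tau)
        kernel /= kernel.sum()  # exact discrete unit area -> charge preserved
        current = np.convolve(current, kernel)[: len(times)]
    trace = AmperometryTrace(times, current, sampling_rate)
    trace = bessel_lowpass(trace, cutoff=bessel_cutoff)
    noisy = noise.apply(trace.times, trace.current)
    return AmperometryTrace(times, noisy, sampling_rate)


def synth_depolarization_recording(
    pool_sizes: tuple[float, float],
    protocol: DepolarizationProtocol | None = None,
    brief_fractions: tuple[float, ...] | None = None,
    long_fractions: tuple[float, ...] | None = None,
    noise: NoiseModel = NoiseModel(),
    sampling_rate: float = DEFAULT_CAP_SAMPLING_HZ,
    tail: float = 0.5,
) -> CapacitanceTrace:
    """Capacitance staircase from a depolarization train.

    ``pool_sizes`` = (irp, rrp_remainder) in fF: the six brief pulses
    cumulatively release the IRP, the four long pulses deplete the
    remaining RRP.  Per-pulse fractions (of the respective pool) default
    to uniform and must each lie in [0, 1] with sums <= 1.  The released
    membrane appears as a linear rise during each pulse and holds between
    pulses.  The ground truth (pool sizes and per-pulse steps) rides
    along on the returned trace.
    """
    irp, rrp_rest = pool_sizes
    if irp < 0 or rrp_rest < 0:
        raise ValueError("pool sizes must be >= 0")
    if protocol is None:
        protocol = default_depolarization_protocol()
    n_brief = sum(1 for d in protocol.pulse_durations if d < 0.05)
    n_long = protocol.n_pulses - n_brief
    if brief_fractions is None:
        brief_fractions = (1.0 / n_brief,) * n_brief if n_brief else ()
    if long_fractions is None:
        long_fractions = (1.0 / n_long,) * n_long if n_long else ()
    if len(brief_fractions) != n_brief or len(long_fractions) != n_long:
        raise ValueError("per-pulse fractions must match the pulse counts")
    for f in (*brief_fractions, *long_fractions):
        if not 0 <= f <= 1:
            raise ValueError("release fractions must lie in [0, 1]")
    if sum(brief_fractions) > 1 + 1e-9 or sum(long_fractions) > 1 + 1e-9:
        raise ValueError("release fractions must sum to <= 1 per pool")

    steps = [irp * f for f in brief_fractions] + [rrp_rest * f for f in long_fractions]
    duration = protocol.pulse_ends[-1] + tail
    n = int(round(duration * sampling_rate))
    times = np.arange(n + 1) / sampling_rate
    values = np.zeros(n + 1)
    for start, end, step in zip(protocol.pulse_starts, protocol.pulse_ends, steps):
        ramp = np.clip((times - start) / (end - start), 0.0, 1.0)
        values += step * ramp
    values = noise.apply(times, values)
    truth = {"irp_fF": irp, "rrp_remainder_fF": rrp_rest, "steps_fF": steps}
    return CapacitanceTrace(times, values, protocol, sampling_rate, ground_truth=truth)
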