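"""Three-pool model of calcium-dependent vesicle priming and fusion.

Large dense-core vesicles are recruited from a Depot reservoir into a
Slowly Releasable Pool (SRP, priming step 1) and from there into a
Readily Releasable Pool (RRP, priming step 2); both priming steps are
reversible.  At rest the pre-stimulus dynamics are

    dSRP/dt = k1*Depot + k_-2*RRP - (k_-1 + k2)*SRP
    dRRP/dt = k2*SRP - k_-2*RRP

and a step rise in intracellular calcium (flash photolysis of a caged
compound) switches on fusion, draining the primed pools into the
membrane: the RRP fuses with rate gamma_fast (the reciprocal of the
fast-burst time constant) and the SRP either fuses directly with
gamma_slow (parallel topology) or matures through the RRP before fusing
(sequential topology).  Cumulative fused membrane is what a whole-cell
capacitance measurement reports.

Setting the time derivatives to zero yields the resting pool sizes

    SRP0 = k1*Depot / k_-1          RRP0 = (k2/k_-2) * SRP0

from which the forward priming propensities are defined:
p1 = k1*Depot/k_-1 = SRP0 (units of membrane, fF) for the upstream step
and p2 = k2/k_-2 = RRP0/SRP0 (dimensionless) for the downstream step.
Because the system is linear, time courses are propagated with exact
matrix exponentials; the output grid spacing controls sampling only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Topology",
    "PoolModelParams",
    "PoolState",
    "PoolTrajectory",
    "PrimingPropensities",
    "DegenerateSteadyStateError",
    "ResolutionError",
    "steady_state_pools",
    "slowest_relaxation_time",
    "simulate_time_course",
    "priming_propensities",
    "propensity_ratio",
    "hill_scale",
]


class Topology(str, Enum):
    """Fate of SRP vesicles after the calcium step.

    PARALLEL: SRP vesicles fuse directly with rate gamma_slow.
    SEQUENTIAL: SRP vesicles mature into the RRP (via k2) and fuse from
    there; only the RRP carries a fusion rate.
    """

    PARALLEL = "parallel"
    SEQUENTIAL = "sequential"


class DegenerateSteadyStateError(ValueError):
    """Raised when a steady state is requested but an unpriming rate is zero."""


class ResolutionError(ValueError):
    """Raised when the output grid cannot resolve the fastest rate in the model."""


@dataclass(frozen=True)
class PoolModelParams:
    """Rate constants and pool sizes of the Depot -> SRP -> RRP -> fused scheme.

    Parameters
    ----------
    depot : float
        Depot pool size (fF of vesicle membrane).  By default the Depot is
        treated as an inexhaustible reservoir, so only the product
        ``k1 * depot`` (a constant priming influx, fF/s) matters; set
        ``finite_depot=True`` to make it a depletable state.
    k1, k_minus1 : float
        Forward / backward rates of priming step 1 (Depot <-> SRP), 1/s.
    k2, k_minus2 : float
        Forward / backward rates of priming step 2 (SRP <-> RRP), 1/s.
    gamma_fast : float
        Post-stimulus fusion rate of the RRP, 1/s (reciprocal of the
        fast-burst time constant).
    gamma_slow : float
        Post-stimulus fusion rate of the SRP, 1/s; used only with the
        parallel topology.
    topology : Topology
        Whether SRP vesicles fuse directly or mature through the RRP.
    finite_depot : bool
        Treat the Depot as a closed, depletable pool (mass conserved).
    """

    depot: float
    k1: float
    k_minus1: float
    k2: float
    k_minus2: float
    gamma_fast: float
    gamma_slow: float = 0.0
    topology: Topology = Topology.PARALLEL
    finite_depot: bool = False

    def __post_init__(self) -> None:
        for name in ("depot", "k1", "k_minus1", "k2", "k_minus2", "gamma_fast", "gamma_slow"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        object.__setattr__(self, "topology", Topology(self.topology))

    @property
    def influx(self) -> float:
        """Constant priming influx J = k1 * Depot (fF/s) in the infinite-depot mode."""
        return self.k1 * self.depot


@dataclass(frozen=True)
class PoolState:
    """Instantaneous pool occupancies (fF of vesicle membrane)."""

    depot: float
    srp: float
    rrp: float
    fused: float = 0.0

    def __post_init__(self) -> None:
        for name in ("depot", "srp", "rrp", "fused"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def total(self) -> float:
        return self.depot + self.srp + self.rrp + self.fused


@dataclass(frozen=True)
class PoolTrajectory:
    """Sampled time course of the pool system.

    ``capacitance`` is the cumulative fused membrane at each time point,
    i.e. what a capacitance recording tracks (relative to baseline).
    """

    times: np.ndarray
    depot: np.ndarray
    srp: np.ndarray
    rrp: np.ndarray
    fused: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        for name in ("depot", "srp", "rrp", "fused"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match times in shape")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "times", t)

    @property
    def capacitance(self) -> np.ndarray:
        return self.fused

    def state_at(self, index: int) -> PoolState:
        return PoolState(
            depot=float(max(self.depot[index], 0.0)),
            srp=float(max(self.srp[index], 0.0)),
            rrp=float(max(self.rrp[index], 0.0)),
            fused=float(max(self.fused[index], 0.0)),
        )

    def final_state(self) -> PoolState:
        return self.state_at(-1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "depot_fF": self.depot,
                "srp_fF": self.srp,
                "rrp_fF": self.rrp,
                "fused_fF": self.fused,
            }
        )


@dataclass(frozen=True)
class PrimingPropensities:
    """Steady-state forward priming propensities.

    p1 = k1*Depot/k_-1 (fF): propensity of the upstream step, equal to the
    resting SRP size.  p2 = k2/k_-2 (dimensionless): propensity of the
    downstream step, equal to the resting RRP/SRP ratio.
    """

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.p1 < 0 or self.p2 < 0:
            raise ValueError("propensities must be >= 0")


def hill_scale(ca_nm: float, ec50_nm: float, h: float = 1.0) -> float:
    """Optional Hill-type modulation factor for a calcium-dependent rate.

    Returns ca^h / (ec50^h + ca^h) in [0, 1).  The model itself treats
    rates as per-condition constants; this hook exists for simulation
    studies that want to impose a calcium dependence on k1 or k2.
    """
    if ca_nm < 0 or ec50_nm <= 0 or h <= 0:
        raise ValueError("require ca_nm >= 0, ec50_nm > 0, h > 0")
    if ca_nm == 0:
        return 0.0
    return 1.0 / (1.0 + (ec50_nm / ca_nm) ** h)


def steady_state_pools(params: PoolModelParams) -> PoolState:
    """Resting pool sizes with fusion switched off.

    SRP0 = k1*Depot/k_-1 and RRP0 = (k2/k_-2)*SRP0; the Depot is passed
    through unchanged (its product with k1 is treated as a constant
    influx) and nothing has fused yet.
    """
    if params.k_minus1 <= 0 or params.k_minus2 <= 0:
        raise DegenerateSteadyStateError(
            "steady state requires k_minus1 > 0 and k_minus2 > 0 "
            f"(got k_minus1={params.k_minus1}, k_minus2={params.k_minus2})"
        )
    srp0 = params.influx / params.k_minus1
    rrp0 = (params.k2 / params.k_minus2) * srp0
    return PoolState(depot=params.depot, srp=srp0, rrp=rrp0, fused=0.0)


def priming_propensities(srp0: float, rrp0: float) -> PrimingPropensities:
    """Propensities from resting pool sizes: p1 = SRP0, p2 = RRP0/SRP0."""
    if srp0 < 0 or rrp0 < 0:
        raise ValueError("pool sizes must be >= 0")
    if srp0 == 0:
        if rrp0 > 0:
            raise ValueError("p2 = RRP0/SRP0 is undefined for SRP0 = 0 with RRP0 > 0")
        return PrimingPropensities(p1=0.0, p2=0.0)
    return PrimingPropensities(p1=srp0, p2=rrp0 / srp0)


def propensity_ratio(
    a: PrimingPropensities, b: PrimingPropensities
) -> tuple[float, float]:
    """Elementwise propensity ratios a/b.

    Used both for condition-vs-condition comparison at a fixed basal
    calcium level and for high-vs-low calcium within one condition.
    """
    if b.p1 <= 0 or b.p2 <= 0:
        raise ZeroDivisionError("reference propensities must be > 0")
    return (a.p1 / b.p1, a.p2 / b.p2)


def slowest_relaxation_time(params: PoolModelParams) -> float:
    """Longest relaxation time (s) of the resting SRP/RRP subsystem.

    The slow eigenvalue of the 2x2 pre-stimulus generator can be much
    slower than min(k_-1, k_-2); use this to choose an integration
    horizon when approaching the steady state numerically.
    """
    if params.k_minus1 <= 0 or params.k_minus2 <= 0:
        raise DegenerateSteadyStateError("relaxation requires positive unpriming rates")
    m = np.array(
        [
            [-(params.k_minus1 + params.k2), params.k_minus2],
            [params.k2, -params.k_minus2],
        ]
    )
    eigvals = np.linalg.eigvals(m)
    return float(1.0 / np.min(np.abs(eigvals.real)))


def _generator(params: PoolModelParams, *, fusing: bool, repriming: bool) -> np.ndarray:
    """Affine generator on the augmented state [depot, srp, rrp, fused, 1]."""
    k1 = params.k1 if repriming else 0.0
    km1 = params.k_minus1 if repriming else 0.0
    k2 = params.k2 if repriming else 0.0
    km2 = params.k_minus2 if repriming else 0.0
    # sequential topology: after the stimulus SRP keeps maturing via k2 even
    # when repriming of upstream steps is frozen
    if fusing and params.topology is Topology.SEQUENTIAL and not repriming:
        k2 = params.k2
    gf = params.gamma_fast if fusing else 0.0
    gs = params.gamma_slow if (fusing and params.topology is Topology.PARALLEL) else 0.0

    A = np.zeros((5, 5))
    if params.finite_depot:
        A[0, 0] = -k1
        A[0, 1] = km1
        A[1, 0] = k1
    else:
        A[1, 4] = k1 * params.depot  # constant influx J
    A[1, 1] = -(km1 + k2 + gs)
    A[1, 2] = km2
    A[2, 1] = k2
    A[2, 2] = -(km2 + gf)
    A[3, 1] = gs
    A[3, 2] = gf
    return A


def simulate_time_course(
    params: PoolModelParams,
    initial: PoolState,
    stimulus_time: float,
    duration: float,
    dt: float,
    repriming_after_flash: bool = True,
    check_resolution: bool = True,
) -> PoolTrajectory:
    """Integrate the linear pool system through a calcium-step stimulus.

    Fusion rates are zero before ``stimulus_time`` and switch on
    instantaneously at the stimulus.  With ``repriming_after_flash``
    disabled the priming machinery (k1*Depot influx, k_-1, k2, k_-2) is
    frozen at the stimulus, so the primed pools simply drain: in the
    parallel topology the cumulative fused signal is then an exact sum of
    two exponentials.

    Propagation uses the matrix exponential of the (affine) generator per
    output interval and is exact for any step; ``dt`` sets the output grid.
    ``check_resolution`` enforces dt * fastest-rate <= 0.1 so the sampled
    trajectory actually resolves the fastest transient; disable it when
    only widely spaced samples (e.g. a long-time endpoint) are wanted.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (0 <= stimulus_time < duration):
        raise ValueError("require 0 <= stimulus_time < duration")
    rates = [params.k1, params.k_minus1, params.k2, params.k_minus2,
             params.gamma_fast, params.gamma_slow]
    fastest = max(rates)
    if check_resolution and dt * fastest > 0.1:
        raise ResolutionError(
            f"dt={dt} too coarse for fastest rate {fastest}/s "
            "(dt*rate must be <= 0.1; pass check_resolution=False for "
            "exact coarse-grid propagation)"
        )

    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt

    a_pre = _generator(params, fusing=False, repriming=True)
    a_post = _generator(params, fusing=True, repriming=repriming_after_flash)
    prop_pre = expm(a_pre * dt)
    prop_post = expm(a_post * dt)

    x = np.array([initial.depot, initial.srp, initial.rrp, initial.fused, 1.0])
    out = np.empty((n + 1, 5))
    out[0] = x
    for i in range(n):
        t0, t1 = times[i], times[i + 1]
        if t1 <= stimulus_time:
            x = prop_pre @ x
        elif t0 >= stimulus_time:
            x = prop_post @ x
        else:  # interval straddles the stimulus: split exactly
            x = expm(a_pre * (stimulus_time - t0)) @ x
            x = expm(a_post * (t1 - stimulus_time)) @ x
        out[i + 1] = x

    return PoolTrajectory(
        times=times,
        depot=out[:, 0],
        srp=out[:, 1],
        rrp=out[:, 2],
        fused=out[:, 3],
    )


def with_calcium_modulation(
    params: PoolModelParams,
    ca_nm: float,
    ec50_k1_nm: float | None = None,
    ec50_k2_nm: float | None = None,
    h: float = 1.0,
) -> PoolModelParams:
    """Scale k1 and/or k2 by a Hill factor of the basal calcium level.

    Purely a convenience for simulation studies; rates are otherwise
    per-condition constants.
    """
    k1 = params.k1 * (hill_scale(ca_nm, ec50_k1_nm, h) if ec50_k1_nm else 1.0)
    k2 = params.k2 * (hill_scale(ca_nm, ec50_k2_nm, h) if ec50_k2_nm else 1.0)
    return replace(params, k1=k1, k2=k2)
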