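"""Ratiometric calcium calibration for dual-dye fluorimetry.

Intracellular [Ca2+] is read from the ratio of fluorescence excited at
350 and 380 nm in cells loaded with a mixture of a high- and a
low-affinity calcium dye (fura-4F + furaptra), which together span a
large dynamic range.  The mapping from ratio to [Ca2+] is fixed by
infusing cells with standard solutions of known calcium concentration
and fitting a single effective Hill-type curve

    ratio(Ca) = r_min + (r_max - r_min) * Ca^h / (k_eff^h + Ca^h)

whose free cooperativity h absorbs the two-dye mixture.  The standards
fully determine this monotone mapping, which is all downstream analysis
uses; measured ratios are inverted numerically, and ratios outside the
calibrated dynamic range are refused rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "RatioTrace",
    "CalibrationCurve",
    "CalibrationRangeError",
    "fit_calibration",
    "ratio_to_calcium",
    "ratio_trace_to_calcium",
]


class CalibrationRangeError(ValueError):
    """Ratio outside the curve's dynamic range (names the saturated end)."""


@dataclass(frozen=True)
class RatioTrace:
    """Sampled 350/380 nm fluorescence ratio, optionally with raw channels."""

    times: np.ndarray
    ratio: np.ndarray
    f350: np.ndarray | None = None
    f380: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        r = np.asarray(self.ratio, float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("times and ratio must be matching 1-D arrays")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("ratios must be finite and > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratio", r)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone effective-Hill mapping between [Ca2+] and fluorescence ratio."""

    r_min: float  # ratio at zero calcium
    r_max: float  # ratio at saturating calcium
    k_eff: float  # nM, effective half-saturation
    h: float  # effective cooperativity
    valid_range: tuple[float, float]  # nM, span of the standards

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("require r_min < r_max")
        if self.k_eff <= 0 or self.h <= 0:
            raise ValueError("require k_eff > 0 and h > 0")

    def forward(self, ca_nm) -> np.ndarray | float:
        """Predicted ratio at the given [Ca2+] (nM)."""
        ca = np.asarray(ca_nm, float)
        sat = ca**self.h / (self.k_eff**self.h + ca**self.h)
        out = self.r_min + (self.r_max - self.r_min) * sat
        return float(out) if out.ndim == 0 else out


def _hill(ca, r_min, r_max, k_eff, h):
    return r_min + (r_max - r_min) * ca**h / (k_eff**h + ca**h)


def fit_calibration(standards: list[tuple[float, float]]) -> CalibrationCurve:
    """Fit the effective Hill curve to (ca_nM, ratio) standards.

    Requires at least four standards spanning at least two orders of
    magnitude in [Ca2+], with ratios increasing in calcium (the physical
    direction of the 350/380 ratio).
    """
    pts = sorted((float(c), float(r)) for c, r in standards)
    if len(pts) < 4:
        raise ValueError("need at least 4 calibration standards")
    ca = np.array([p[0] for p in pts])
    ratio = np.array([p[1] for p in pts])
    if np.any(ca <= 0):
        raise ValueError("standard calcium concentrations must be > 0")
    if ca[-1] / ca[0] < 100:
        raise ValueError("standards must span >= 2 orders of magnitude in calcium")
    if np.any(np.diff(ratio) <= 0):
        raise ValueError("standard ratios must increase monotonically with calcium")

    span = ratio[-1] - ratio[0]
    p0 = [max(ratio[0] - 0.05 * span, 1e-6), ratio[-1] + 0.05 * span,
          float(np.sqrt(ca[0] * ca[-1])), 1.0]
    lower = [0.0, ratio[-1] * 0.5, ca[0] * 1e-3, 0.2]
    upper = [ratio[0] * 1.5, ratio[-1] * 10.0, ca[-1] * 1e3, 5.0]
    popt, _ = curve_fit(_hill, ca, ratio, p0=p0, bounds=(lower, upper), maxfev=20000)
    r_min, r_max, k_eff, h = (float(v) for v in popt)
    return CalibrationCurve(r_min, r_max, k_eff, h, valid_range=(float(ca[0]), float(ca[-1])))


def ratio_to_calcium(curve: CalibrationCurve, ratio: float) -> float:
    """Invert the calibration curve for a single measured ratio (nM).

    Bisection on the strictly monotone forward model; round trips within
    the valid range are accurate to well below 0.5%.
    """
    if ratio <= curve.r_min:
        raise CalibrationRangeError(
            f"ratio {ratio:.4g} at or below r_min={curve.r_min:.4g} "
            "(zero-calcium asymptote): [Ca2+] unresolvable at the low end"
        )
    if ratio >= curve.r_max:
        raise CalibrationRangeError(
            f"ratio {ratio:.4g} at or above r_max={curve.r_max:.4g} "
            "(saturating-calcium asymptote): [Ca2+] unresolvable at the high end"
        )
    # closed-form bracket from the Hill form, then polish by bisection
    sat = (ratio - curve.r_min) / (curve.r_max - curve.r_min)
    ca_guess = curve.k_eff * (sat / (1.0 - sat)) ** (1.0 / curve.h)
    lo, hi = ca_guess / 2.0, ca_guess * 2.0
    while curve.forward(lo) > ratio:
        lo /= 2.0
    while curve.forward(hi) < ratio:
        hi *= 2.0
    return float(brentq(lambda c: curve.forward(c) - ratio, lo, hi, xtol=1e-12, rtol=1e-12))


def ratio_trace_to_calcium(curve: CalibrationCurve, trace: RatioTrace) -> np.ndarray:
    """Pointwise inversion of a ratio trace to [Ca2+] in nM."""
    return np.array([ratio_to_calcium(curve, float(r)) for r in trace.ratio])
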