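"""Variance-gated statistical decision trees for per-cell secretion measures.

Two groups: an F-test on the variance ratio gates between an unpaired
two-tailed Student's t-test (equal variances not rejected) and a
Mann-Whitney rank test.  Three groups: Bartlett's homoscedasticity test
gates between one-way ANOVA with Tukey's HSD post-hoc and
Kruskal-Wallis with Dunn's rank post-hoc.  Membrane-translocation
imaging is summarised by the total/cytosol intensity ratio; its change
upon stimulation is tested against zero with a one-sample t-test.

Gate tests use a two-sided alpha of 0.05 by default and all components
(gate, omnibus, post-hoc) are reported, never just the branch outcome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "OneSampleResult",
    "TranslocationMeasure",
    "compare_two_groups",
    "compare_three_groups",
    "dunn_posthoc",
    "translocation_test",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    """Gate, main and (for >= 3 groups) post-hoc components of a comparison."""

    branch_taken: str  # "parametric" | "nonparametric"
    gate_test: str
    gate_statistic: float
    gate_p: float
    main_test: str
    main_statistic: float
    main_p: float
    alpha: float
    posthoc_test: str | None = None
    posthoc: tuple[tuple[tuple[int, int], float], ...] | None = None

    def __post_init__(self) -> None:
        for p in (self.gate_p, self.main_p):
            if not 0 <= p <= 1:
                raise ValueError("p-values must lie in [0, 1]")
        expected = "nonparametric" if self.gate_p < self.alpha else "parametric"
        if self.branch_taken != expected:
            raise ValueError("branch_taken inconsistent with gate_p vs alpha")

    @property
    def significant(self) -> bool:
        return self.main_p < self.alpha


@dataclass(frozen=True)
class OneSampleResult:
    statistic: float
    p_value: float
    mean: float
    n: int


@dataclass(frozen=True)
class TranslocationMeasure:
    """Membrane-translocation readout: total/cytosol fluorescence ratio.

    The ratio is >= 1 whenever the total region contains the cytosolic
    one; delta_vs_rest is the change in the ratio after stimulation.
    """

    ratio: float
    delta_vs_rest: float = 0.0

    @staticmethod
    def from_intensities(total: float, cytosol: float) -> "TranslocationMeasure":
        if cytosol <= 0:
            raise ValueError("cytosol intensity must be > 0")
        return TranslocationMeasure(ratio=total / cytosol)

    def with_stimulated(self, stim_ratio: float) -> "TranslocationMeasure":
        return TranslocationMeasure(ratio=self.ratio, delta_vs_rest=stim_ratio - self.ratio)


def _as_sample(x, name: str) -> np.ndarray:
    a = np.asarray(x, float).ravel()
    if len(a) < 3:
        raise ValueError(f"{name} needs n >= 3, got {len(a)}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _variance_ratio_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test on the ratio of sample variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0, 1.0
    if vb == 0 or va == 0:
        return math.inf, 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    return float(f), float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def compare_two_groups(a, b, alpha: float = 0.05) -> GroupComparisonResult:
    """F-test gate, then Student's t (pooled variance) or Mann-Whitney."""
    a = _as_sample(a, "group a")
    b = _as_sample(b, "group b")
    f_stat, f_p = _variance_ratio_test(a, b)
    if f_p < alpha:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparisonResult(
            branch_taken="nonparametric",
            gate_test="F-test (variance ratio)",
            gate_statistic=f_stat,
            gate_p=f_p,
            main_test="Mann-Whitney U",
            main_statistic=float(stat),
            main_p=float(p),
            alpha=alpha,
        )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        t_stat, t_p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (math.inf, 0.0)
    else:
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparisonResult(
        branch_taken="parametric",
        gate_test="F-test (variance ratio)",
        gate_statistic=f_stat,
        gate_p=f_p,
        main_test="Student's t (unpaired, two-tailed)",
        main_statistic=float(t_stat),
        main_p=float(t_p),
        alpha=alpha,
    )


def dunn_posthoc(groups: list[np.ndarray]) -> list[tuple[tuple[int, int], float]]:
    """Dunn's pairwise rank comparisons with midranks, tie correction and
    Bonferroni adjustment across all pairs."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)  # midranks
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i]: offsets[i + 1]])) for i in range(len(groups))
    ]
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(((i, j), float(min(1.0, p * n_pairs))))
    return out


def compare_three_groups(
    groups, alpha: float = 0.05, allow_other_k: bool = False, posthoc: bool = True
) -> GroupComparisonResult:
    """Bartlett gate, then ANOVA + Tukey HSD or Kruskal-Wallis + Dunn.

    Designed for the three-condition layout (control / expressed /
    mutant); other group counts are refused unless ``allow_other_k``.
    ``posthoc=False`` skips the pairwise stage (Tukey's studentized-range
    p-values are comparatively expensive) when only the omnibus decision
    is needed, e.g. in calibration simulations.
    """
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) != 3 and not allow_other_k:
        raise ValueError(
            f"procedure is defined for 3 groups (got {len(samples)}); "
            "pass allow_other_k=True to extend it"
        )
    bart_stat, bart_p = stats.bartlett(*samples)
    if bart_p < alpha:
        kw_stat, kw_p = stats.kruskal(*samples)
        pairs = tuple(dunn_posthoc(samples)) if posthoc else None
        return GroupComparisonResult(
            branch_taken="nonparametric",
            gate_test="Bartlett",
            gate_statistic=float(bart_stat),
            gate_p=float(bart_p),
            main_test="Kruskal-Wallis",
            main_statistic=float(kw_stat),
            main_p=float(kw_p),
            alpha=alpha,
            posthoc_test="Dunn (Bonferroni-adjusted)" if posthoc else None,
            posthoc=pairs,
        )
    an_stat, an_p = stats.f_oneway(*samples)
    if posthoc:
        tukey = stats.tukey_hsd(*samples)
        pairs = tuple(
            ((i, j), float(tukey.pvalue[i, j]))
            for i, j in itertools.combinations(range(len(samples)), 2)
        )
    else:
        pairs = None
    return GroupComparisonResult(
        branch_taken="parametric",
        gate_test="Bartlett",
        gate_statistic=float(bart_stat),
        gate_p=float(bart_p),
        main_test="one-way ANOVA",
        main_statistic=float(an_stat),
        main_p=float(an_p),
        alpha=alpha,
        posthoc_test="Tukey HSD" if posthoc else None,
        posthoc=pairs,
    )


def translocation_test(deltas, alpha: float = 0.05) -> OneSampleResult:
    """Two-sided one-sample t-test of translocation deltas against zero."""
    d = _as_sample(deltas, "deltas")
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return OneSampleResult(statistic=0.0, p_value=1.0, mean=0.0, n=len(d))
        return OneSampleResult(
            statistic=math.copysign(math.inf, d[0]), p_value=0.0, mean=float(d[0]), n=len(d)
        )
    stat, p = stats.ttest_1samp(d, 0.0)
    return OneSampleResult(
        statistic=float(stat), p_value=float(p), mean=float(np.mean(d)), n=len(d)
    )
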