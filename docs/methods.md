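# Methods

## The three-pool priming model

The model tracks vesicle membrane (in fF of capacitance equivalent)
through a reservoir (Depot), a Slowly Releasable Pool (SRP) and a
Readily Releasable Pool (RRP). Pre-stimulus dynamics are linear:

    dSRP/dt = k1·Depot + k−2·RRP − (k−1 + k2)·SRP
    dRRP/dt = k2·SRP − k−2·RRP

By default the Depot is an inexhaustible reservoir, so only the constant
influx J = k1·Depot enters the equations; a `finite_depot` mode makes
the Depot a depletable state (with d(Depot)/dt = −k1·Depot + k−1·SRP)
for mass-conservation checks. A calcium step at `stimulus_time`
instantaneously switches on fusion: γ_fast drains the RRP and — in the
parallel topology — γ_slow drains the SRP; in the sequential topology
the SRP instead empties through the RRP via k2. The fusion rates are the
reciprocals of the fast/slow burst time constants. Cage photochemistry
is not modelled; the flash is a rate switch.

The parallel topology is the default because it makes the decomposition
identity exact (fast amplitude = RRP0, slow amplitude = SRP0). Whether
SRP vesicles fuse directly or mature first is not experimentally
resolved, so both topologies are implemented and neither is privileged
in any derived quantity.

Steady state (fusion off, k−1 > 0, k−2 > 0):

    SRP0 = k1·Depot/k−1      RRP0 = (k2/k−2)·SRP0

and the priming propensities are p1 = SRP0 (fF) and p2 = RRP0/SRP0
(dimensionless). Zero unpriming rates make the steady state degenerate
and raise an error rather than returning infinities.

**Calcium dependence.** No functional form for how basal [Ca²⁺]
modulates k1 or k2 is imposed; rates are per-condition constants, and
propensities are compared *empirically* between calcium levels. A
Hill-factor hook (`hill_scale`, `with_calcium_modulation`) exists for
simulation studies but is never fitted.

**Integration.** The system is linear, so each output interval is
propagated by the matrix exponential of the (affine-augmented)
generator — exact to machine precision for any step size, with no
solver tolerance to choose. The output grid `dt` therefore controls
sampling only; a guard (`dt·max_rate ≤ 0.1`) still rejects grids too
coarse to resolve the fastest transient, and can be disabled when only
widely spaced samples are wanted (e.g. approaching the steady state).
Note that the slowest relaxation eigenvalue of the SRP/RRP subsystem can
be far slower than min(k−1, k−2); `slowest_relaxation_time` computes it,
and steady-state comparisons integrate to 25 of those relaxation times.

## Synthetic recordings

The generator's defaults are the study conditions every test and the
acceptance script run under:

| parameter | default | rationale |
| --- | --- | --- |
| capacitance sampling | 1 kHz | resolves τ ≥ 10 ms; the acquisition rate is not reported |
| capacitance noise σ | 5 fF | order-of-magnitude instrument noise; configurable |
| reference truth | 150 fF/20 ms, 150 fF/150 ms, 40 fF/s | mid-range of the reported τ windows and typical burst/sustained sizes |
| sustained phase | pure linear ramp | the sustained τ approaches/exceeds the 5 s window, so only its mean linear rate is meaningful; an exponential-sustained mode (τ ≥ 1 s) exists for robustness checks |
| amperometric sampling / filter | 11.5 kHz, 7-pole Bessel at 1 kHz | the stated acquisition chain |
| diffusional delay | single exponential, τ = 50 ms, unit area | simplest causal kernel reproducing the fast/slow indistinguishability in amperometric currents; unit area preserves charge |
| charge per fused fF | 0.002 pC/fF | round order-of-magnitude scale; only products α·ΔCm are ever asserted |
| depolarization train | 6×10 ms + 4×100 ms, −70→+20 mV, 100 ms gaps | the stated IRP/RRP protocol; inter-pulse gap chosen to leave room for pre/post-pulse baselines |
| flash calcium step | instantaneous, pre in nM / post in µM | the uncaging light lasts 1–2 ms, negligible vs. τ_fast |

Noise is i.i.d. Gaussian with an optional linear drift; pink noise and
single-spike amperometric structure (feet, quantal sizes) are out of
scope. Consequently, passing recovery tests demonstrates estimator
correctness under well-specified noise — not robustness to gating
artifacts, conductance crosstalk, baseline wander or non-stationary
noise found in real recordings. Determinism is strict: a `NoiseModel`
with σ > 0 requires an explicit seed, and identical seeds give
bit-identical traces.

## Trace decomposition

Flash responses are fit over the flash→flash+5 s window, equally
weighted, with Cm(t′) = A_fast(1−e^(−t′/τ_fast)) +
A_slow(1−e^(−t′/τ_slow)) + m·t′, baseline taken as the mean of the
100 ms immediately pre-flash. Choices worth knowing:

- **τ bounds** are [5, 50] ms and [50, 500] ms — deliberately wider than
  the descriptive 10–30 / 70–300 ms windows so estimates are not pinned
  to bounds; whether a fitted τ lands in the typical window is a QC flag
  (`qc_flags()`), not a constraint.
- **Initialisation:** 3×3 log-spaced τ grid with amplitudes solved by
  non-negative linear least squares (the model is linear given the τs);
  the best seed is refined by a bounded trust-region fit. Ordering
  τ_fast < τ_slow is enforced by sorting after the fit.
- **Degeneracy:** if the two burst τs approach within 10 ms the trace
  cannot support two components; it is refit with a single burst + ramp,
  the merged amplitude reported as the slow burst, and the result
  flagged `degenerate` (pool mapping then refuses it).
- **Sustained term:** linear by default — the reported quantity is the
  mean linear rate within 5 s. The exponential-sustained option (τ ≥ 1 s)
  converts its amplitude back to a mean linear rate over the window so
  downstream consumers see one consistent quantity.
- Non-convergence sets `converged=False` with the residual retained;
  it is never silent.

Window measures are model-free: burst = Cm(flash+0.5 s) − baseline,
sustained rate = [Cm(flash+5 s) − Cm(flash+0.5 s)]/4.5. The window burst
systematically undercounts slow-burst tails relative to the fitted
amplitudes; the direction of that bias is asserted in tests. IRP/RRP
staircase measures use inter-pulse baselines only, since capacitance
sampled during a depolarization is unreliable.

## Calcium calibration

The dual-dye mixture has no single textbook equation; since downstream
analysis only ever uses the monotone ratio↔[Ca²⁺] mapping, a single
effective Hill curve (r_min, r_max, k_eff, h free) is fit to the
standards (≥ 4 points spanning ≥ 2 decades, monotonicity enforced).
Inversion brackets the root from the closed-form Hill inverse and
polishes with Brent's method; ratios at or beyond the asymptotes raise a
range error naming the saturated end — extrapolation is refused, never
clamped. Pooled calibration is the default; per-cell curves are just
separate `fit_calibration` calls.

## Amperometry

The digital Bessel filter is scipy's bilinear-transform realisation with
frequency prewarping; initial conditions are the steady state of the
first sample, so DC gain is exactly unity and in-band charge is
conserved (< 1% change, asserted). Charge is the trapezoidal cumulative
integral (pA·s = pC). Charge/capacitance agreement reports the
least-squares scale α and the RMS residual normalised to peak charge;
flat inputs are refused as the scale is undefined. The baseline window
(0.5 s pre-stimulus median) is a package choice; the original window
length is unreported.

## Statistical workflow

Two groups: two-sided F-test on the variance ratio at α = 0.05 gates
between the pooled-variance t-test and Mann-Whitney. Three groups:
Bartlett's test gates between ANOVA + Tukey HSD and Kruskal-Wallis +
Dunn. Dunn's comparisons use midranks, the tie-corrected standard error,
and Bonferroni adjustment across the three pairs (the correction used
originally is unstated; Bonferroni is the common convention and is
conservative). The three-group procedure refuses other group counts
unless explicitly extended (`allow_other_k`), and `posthoc=False` skips
the pairwise stage when only the omnibus decision is needed (Tukey's
studentized-range p-values dominate runtime in calibration loops). Both
trees are empirically calibrated: under Gaussian nulls the overall
rejection rate sits within [0.04, 0.06] at 2000 replicates (recomputed
by the acceptance script). Degenerate edge cases (all-zero translocation
deltas, two zero-variance groups) return exact p = 1 / p = 0 rather than
NaN.

## Pipeline and problem sizes

`run_pipeline` derives one seed per cell from the config seed via
`SeedSequence` spawning, so batches are reproducible bit-for-bit and
every report embeds the config hash. A failing cell is flagged and
skipped; an empty condition aborts. Propensities are computed from
per-condition *mean* pools (the estimator used originally), then ratioed
against the reference condition.

Problem sizes used by the test suite and `scripts/acceptance.py` —
500 steady-state draws, 100 closed-form and noiseless-fit cases, 100
noisy replicates, 20 cells/condition for the propensity-ratio study,
2000 replicates per decision tree — are the package's chosen standard
study; they give Monte-Carlo margins comfortably inside every asserted
tolerance while keeping a full run in seconds.

## Known limitations

- The propensity calculus assumes pools are equilibrated before the
  flash, J = k1·Depot constant, and no pre-stimulus fusion; violations
  bias p1 and p2 in ways the package does not detect.
- Amplitude identities (A_fast = RRP0, A_slow = SRP0) are exact only in
  the parallel topology; under sequential fusion the decomposition is an
  approximation.
- The synthetic noise model is stationary and Gaussian; recovery
  statistics do not transfer to recordings with artifacts.
- No stochastic (discrete-vesicle) simulation, no spike-level
  amperometric analysis, no rate-constant fitting to traces (pool sizes,
  not rates, are the measured quantities).
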