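# primekin

Quantitative analysis of calcium-triggered large-dense-core-vesicle
exocytosis, built around whole-cell membrane-capacitance recordings from
adrenal chromaffin cells.

Secretion probed by flash photolysis of caged calcium proceeds in
kinetically distinct phases: a fast exocytotic burst (τ ≈ 10–30 ms)
reflecting fusion of the Readily Releasable Pool (RRP), a slow burst
(τ ≈ 70–300 ms) from the Slowly Releasable Pool (SRP), and a near-linear
sustained phase driven by ongoing priming. `primekin` packages the full
analysis chain for this kind of experiment — and, because such raw
recordings are rarely shared, a seeded synthetic-data generator with
known ground truth to exercise it.

## The model

Vesicles mature through two reversible priming steps,

```
          k1            k2            γ_fast
  Depot ⇌ SRP  ⇌  RRP  ──→  fused
          k-1           k-2
```

with fusion rates switched on by the calcium step (the SRP either fuses
directly with rate γ_slow — the parallel topology — or matures through
the RRP; both are implemented). Setting dSRP/dt = dRRP/dt = 0 at rest
gives

```
  SRP0 = k1·Depot / k-1          RRP0 = (k2/k-2) · SRP0
```

so two *priming propensities* are measurable from a capacitance trace
alone: **p1 = k1·Depot/k−1 = SRP0** (the slow-burst amplitude, in fF)
for the upstream step, and **p2 = k2/k−2 = RRP0/SRP0** (the fast/slow
amplitude ratio, dimensionless) for the downstream step. Comparing
propensity ratios between genotypes, or between basal calcium levels
within a genotype, localises where an intervention acts in the priming
cascade.

## What's in the package

| module | contents |
| --- | --- |
| `pool_model` | exact (matrix-exponential) forward simulation, steady state, propensities and their ratios |
| `synthetic_data` | seeded generators: flash capacitance responses, calcium steps, diffusion-delayed amperometry, 6×10 ms + 4×100 ms depolarization staircases |
| `kinetics_fit` | triple-exponential decomposition A(1−e^(−t/τ)), window burst measures (0.5 s burst, 0.5–5 s sustained rate), IRP/RRP staircase measures |
| `calcium_calib` | effective-Hill calibration of dual-dye 350/380 ratios against standards, with refuse-don't-clamp inversion |
| `amperometry` | 7-pole Bessel low-pass (1 kHz), charge integration, charge-vs-capacitance agreement |
| `stats_workflow` | F-test→t/Mann-Whitney and Bartlett→ANOVA+Tukey / Kruskal+Dunn decision trees, one-sample translocation test |
| `io` / `cli` | CSV+JSON trace formats, experiment configs, the end-to-end pipeline, `primekin` console command |

## Worked example

Two synthetic conditions — a knockout baseline and a rescue whose
downstream priming equilibrium k2/k−2 is doubled — analysed end to end
(12 cells each, 5 fF noise):

```python
from primekin.io import ConditionSpec, ExperimentConfig, run_pipeline
from primekin.synthetic_data import FlashProtocol

base = dict(depot=1000.0, k1=0.01, k_minus1=0.05, k2=0.05, k_minus2=0.05,
            gamma_fast=50.0, gamma_slow=1/0.15)
config = ExperimentConfig(
    conditions=(
        ConditionSpec(label="KO", n_cells=12, pool_params=base),
        ConditionSpec(label="rescue", n_cells=12, pool_params=dict(base, k2=0.10)),
    ),
    seed=7,
    protocol=FlashProtocol(flash_time=0.5, duration=6.0),
    noise_sigma_ff=5.0,
)
result = run_pipeline(config)
```

`result` then holds the per-cell table, per-condition propensities,
ratios and statistics; formatting them gives:

```
KO:     n=12  SRP0=199.9 fF  RRP0=199.9 fF  p1=199.9 fF  p2=1.00
rescue: n=12  SRP0=199.7 fF  RRP0=400.3 fF  p1=199.7 fF  p2=2.00
rescue vs KO: ratio_p1=0.999  ratio_p2=2.004
a_fast: Student's t (unpaired, two-tailed) p=1.45e-36 (parametric branch)
config hash: 2b8c21f9c449af27
```

Read: each cell's capacitance trace was decomposed into fast/slow bursts
and a sustained ramp; mean amplitudes give per-condition resting pools;
the recovered downstream propensity ratio (2.004) matches the 2-fold
k2/k−2 difference built into the generator, while the upstream
propensity is unchanged (0.999) — exactly the dissociation the
propensity calculus is designed to expose. The fast-burst increase is
highly significant on the parametric branch of the decision tree.

The same flow is available from the shell:

```
primekin run --config config.json --outdir out/
primekin fixtures --config config.json --outdir traces/
primekin fit --indir traces/ --out results.csv
primekin calibrate --standards standards.csv --curve-out curve.json
```

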