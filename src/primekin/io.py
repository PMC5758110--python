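"""File formats, experiment configuration and the end-to-end pipeline.

Traces travel as two-column CSV (time, value) with a JSON sidecar that
carries the signal kind, units, sampling rate, stimulus protocol, seed
and — for generated data — the ground truth.  Units are converted to
the canonical set (s, fF, pA, nM) at the I/O boundary only.

``run_pipeline`` glues the modules into the full analysis flow: per-cell
trace generation (or loading), kinetic decomposition, per-condition mean
pool sizes, priming propensities, condition/calcium propensity ratios
and the statistical comparison of per-cell measures.  Every stochastic
step derives its seed from the config seed, so reruns are bit-identical,
and outputs embed the config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinetics_fit, pool_model
from .amperometry import AmperometryTrace
from .calcium_calib import RatioTrace
from .synthetic_data import (
    CapacitanceTrace,
    DepolarizationProtocol,
    FlashProtocol,
    GroundTruth,
    NoiseModel,
    synth_capacitance_trace,
)

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "ConditionSpec",
    "ExperimentConfig",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger("primekin")

_TIME_FACTORS = {"s": 1.0, "ms": 1e-3}
_VALUE_FACTORS = {
    "capacitance": {"fF": 1.0, "pF": 1e3},
    "amperometry": {"pA": 1.0, "nA": 1e3},
    "ratio": {"dimensionless": 1.0, "": 1.0},
    "calcium": {"nM": 1.0, "uM": 1e3},
}


class TraceFormatError(ValueError):
    """Malformed trace file or sidecar."""


def _protocol_to_dict(protocol) -> dict:
    if isinstance(protocol, FlashProtocol):
        return {"type": "flash", **dataclasses.asdict(protocol)}
    if isinstance(protocol, DepolarizationProtocol):
        d = dataclasses.asdict(protocol)
        d["pulse_starts"] = list(d["pulse_starts"])
        d["pulse_durations"] = list(d["pulse_durations"])
        return {"type": "depolarization", **d}
    raise TraceFormatError(f"unknown protocol object {type(protocol).__name__}")


def _protocol_from_dict(d: dict):
    kind = d.get("type")
    fields = {k: v for k, v in d.items() if k != "type"}
    if kind == "flash":
        return FlashProtocol(**fields)
    if kind == "depolarization":
        fields["pulse_starts"] = tuple(fields["pulse_starts"])
        fields["pulse_durations"] = tuple(fields["pulse_durations"])
        return DepolarizationProtocol(**fields)
    raise TraceFormatError(f"sidecar protocol type {kind!r} not recognised")


def write_trace(trace, path, sidecar_path=None) -> None:
    """Write a trace as CSV (canonical units) plus a JSON sidecar."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if isinstance(trace, CapacitanceTrace):
        kind, col, values = "capacitance", "capacitance_fF", trace.values
        unit = "fF"
        sidecar = {
            "protocol": _protocol_to_dict(trace.protocol),
            "sampling_rate_hz": trace.sampling_rate,
        }
        if trace.ground_truth is not None:
            gt = trace.ground_truth
            sidecar["ground_truth"] = (
                dataclasses.asdict(gt) if dataclasses.is_dataclass(gt) else gt
            )
    elif isinstance(trace, AmperometryTrace):
        kind, col, values, unit = "amperometry", "current_pA", trace.current, "pA"
        sidecar = {"sampling_rate_hz": trace.sampling_rate}
    elif isinstance(trace, RatioTrace):
        kind, col, values, unit = "ratio", "ratio", trace.ratio, "dimensionless"
        sidecar = {}
    else:
        raise TraceFormatError(f"cannot serialise {type(trace).__name__}")
    pd.DataFrame({"time_s": trace.times, col: values}).to_csv(path, index=False)
    sidecar = {"kind": kind, "units": {"time": "s", "value": unit}, **sidecar}
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def read_trace(path, sidecar=None):
    """Read a CSV trace with its JSON sidecar into a typed trace object.

    The sidecar must name the signal kind and units; capacitance traces
    additionally need their stimulus protocol (a flash trace without a
    flash_time cannot be analysed).  Values are converted to canonical
    units (s, fF, pA) on the way in.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if not sidecar.exists():
        raise TraceFormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("kind", "units"):
        if key not in meta:
            raise TraceFormatError(f"sidecar lacks required field {key!r}")
    kind = meta["kind"]
    units = meta["units"]
    try:
        t_factor = _TIME_FACTORS[units["time"]]
        v_factor = _VALUE_FACTORS[kind][units["value"]]
    except KeyError as exc:
        raise TraceFormatError(f"unknown unit or kind in sidecar: {exc}") from exc

    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise TraceFormatError("trace CSV needs a time column and a value column")
    times = frame.iloc[:, 0].to_numpy(float) * t_factor
    values = frame.iloc[:, 1].to_numpy(float) * v_factor
    dts = np.diff(times)
    if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise TraceFormatError("trace must be uniformly sampled")

    if kind == "capacitance":
        if "protocol" not in meta:
            raise TraceFormatError("capacitance sidecar must include the stimulus protocol")
        protocol = _protocol_from_dict(meta["protocol"])
        rate = meta.get("sampling_rate_hz", 1.0 / dts[0])
        gt = meta.get("ground_truth")
        if isinstance(gt, dict) and set(gt) == {
            "a_fast", "tau_fast", "a_slow", "tau_slow", "sustained_rate"
        }:
            gt = GroundTruth(**gt)
        return CapacitanceTrace(times, values, protocol, rate, ground_truth=gt)
    if kind == "amperometry":
        rate = meta.get("sampling_rate_hz", 1.0 / dts[0])
        return AmperometryTrace(times, values, rate)
    if kind == "ratio":
        return RatioTrace(times, values)
    raise TraceFormatError(f"unknown trace kind {kind!r}")


# --------------------------------------------------------------------------
# experiment configuration and pipeline


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition (genotype / construct at a calcium level).

    Ground truth may be given directly (burst amplitudes, taus, sustained
    rate) or via pool-model parameters, in which case the resting pool
    sizes set the burst amplitudes, the fusion rates set the time
    constants and the priming influx sets the sustained rate.
    """

    label: str
    n_cells: int
    ground_truth: dict | None = None
    pool_params: dict | None = None
    basal_ca_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if (self.ground_truth is None) == (self.pool_params is None):
            raise ValueError("give exactly one of ground_truth or pool_params")

    def resolve_truth(self, topology: str = "parallel") -> GroundTruth:
        if self.ground_truth is not None:
            return GroundTruth(**self.ground_truth)
        params = pool_model.PoolModelParams(topology=topology, **self.pool_params)
        rest = pool_model.steady_state_pools(params)
        if params.gamma_slow <= 0 or params.gamma_fast <= 0:
            raise ValueError("pool-parameter conditions need positive fusion rates")
        return GroundTruth(
            a_fast=rest.rrp,
            tau_fast=1.0 / params.gamma_fast,
            a_slow=rest.srp,
            tau_slow=1.0 / params.gamma_slow,
            sustained_rate=params.influx,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of a synthetic experiment batch."""

    conditions: tuple[ConditionSpec, ...]
    seed: int
    protocol: FlashProtocol = FlashProtocol(flash_time=0.5)
    noise_sigma_ff: float = 5.0
    sampling_rate_hz: float = 1000.0
    topology: str = "parallel"
    alpha: float = 0.05
    reference_condition: str | None = None  # defaults to the first label

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        d = dict(d)
        conds = tuple(ConditionSpec(**c) for c in d.pop("conditions"))
        proto = d.pop("protocol", None)
        protocol = FlashProtocol(**proto) if proto else FlashProtocol(flash_time=0.5)
        return ExperimentConfig(conditions=conds, protocol=protocol, **d)

    @staticmethod
    def from_file(path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return ExperimentConfig.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "conditions": [dataclasses.asdict(c) for c in self.conditions],
            "seed": self.seed,
            "protocol": dataclasses.asdict(self.protocol),
            "noise_sigma_ff": self.noise_sigma_ff,
            "sampling_rate_hz": self.sampling_rate_hz,
            "topology": self.topology,
            "alpha": self.alpha,
            "reference_condition": self.reference_condition,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    """Per-cell results plus condition-level propensity and stats reports."""

    results_table: pd.DataFrame
    propensities: dict[str, dict]
    ratios: dict[str, dict]
    stats: dict[str, dict]
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "propensities": self.propensities,
            "ratios": self.ratios,
            "stats": self.stats,
        }
        return json.dumps(payload, indent=2, default=float)


_STAT_METRICS = ("a_fast", "a_slow", "sustained_rate", "burst_05s")


def _cell_seeds(config: ExperimentConfig) -> dict[str, list[int]]:
    """Deterministic per-cell seeds spawned from the config seed (< 2^31)."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.conditions))
    out = {}
    for cond, child in zip(config.conditions, children):
        out[cond.label] = [
            int(s) % (2**31) for s in child.generate_state(cond.n_cells)
        ]
    return out


def run_pipeline(config: ExperimentConfig) -> PipelineResult:
    """Generate, decompose and compare all conditions of an experiment.

    Per cell: synthesize the flash response, fit the triple-exponential
    decomposition, take window burst measures and map the fit to pool
    sizes.  Per condition: average the per-cell pools and compute priming
    propensities.  Across conditions: propensity ratios against the
    reference condition and the two-/three-group statistical workflow on
    each per-cell metric.  A failing cell is flagged and skipped, never
    fatal to the batch.
    """
    seeds = _cell_seeds(config)
    rows = []
    for cond in config.conditions:
        truth = cond.resolve_truth(config.topology)
        for i, seed in enumerate(seeds[cond.label]):
            row = {"condition": cond.label, "cell": i, "seed": seed, "qc_ok": False}
            try:
                trace = synth_capacitance_trace(
                    truth,
                    config.protocol,
                    NoiseModel(sigma=config.noise_sigma_ff, seed=seed),
                    sampling_rate=config.sampling_rate_hz,
                )
                bursts = kinetics_fit.measure_bursts(trace)
                fit = kinetics_fit.fit_triple_exponential(trace)
                srp0, rrp0 = kinetics_fit.decomposition_to_pools(fit)
                row.update(
                    burst_05s=bursts.burst_05s,
                    sustained_rate_win=bursts.sustained_rate_win,
                    total_5s=bursts.total_5s,
                    a_fast=fit.a_fast,
                    tau_fast=fit.tau_fast,
                    a_slow=fit.a_slow,
                    tau_slow=fit.tau_slow,
                    sustained_rate=fit.sustained_rate,
                    residual_rms=fit.residual_rms,
                    srp0=srp0,
                    rrp0=rrp0,
                    qc_ok=True,
                    **{f"qc_{k}": v for k, v in fit.qc_flags().items()},
                )
            except Exception as exc:  # graceful degradation, cell flagged
                logger.warning("cell %s/%s failed: %s", cond.label, i, exc)
                row["error"] = str(exc)
            rows.append(row)
    table = pd.DataFrame(rows)
    if "qc_ok" in table and not table["qc_ok"].any():
        raise RuntimeError("every cell failed; check configuration")

    propensities: dict[str, dict] = {}
    for cond in config.conditions:
        sub = table[(table["condition"] == cond.label) & table["qc_ok"]]
        if sub.empty:
            raise RuntimeError(f"condition {cond.label!r} has no usable cells")
        srp0 = float(sub["srp0"].mean())
        rrp0 = float(sub["rrp0"].mean())
        props = pool_model.priming_propensities(srp0, rrp0)
        propensities[cond.label] = {
            "n_cells": int(len(sub)),
            "srp0_fF": srp0,
            "rrp0_fF": rrp0,
            "p1_fF": props.p1,
            "p2": props.p2,
        }

    ref_label = config.reference_condition or config.conditions[0].label
    ref = pool_model.PrimingPropensities(
        propensities[ref_label]["p1_fF"], propensities[ref_label]["p2"]
    )
    ratios: dict[str, dict] = {}
    for label, entry in propensities.items():
        cur = pool_model.PrimingPropensities(entry["p1_fF"], entry["p2"])
        r1, r2 = pool_model.propensity_ratio(cur, ref)
        ratios[label] = {"vs": ref_label, "ratio_p1": r1, "ratio_p2": r2}

    stats_report: dict[str, dict] = {}
    ok = table[table["qc_ok"]]
    groups = [ok[ok["condition"] == c.label] for c in config.conditions]
    if len(groups) in (2, 3) and all(len(g) >= 3 for g in groups):
        from . import stats_workflow

        for metric in _STAT_METRICS:
            samples = [g[metric].to_numpy() for g in groups]
            if len(samples) == 2:
                res = stats_workflow.compare_two_groups(*samples, alpha=config.alpha)
            else:
                res = stats_workflow.compare_three_groups(samples, alpha=config.alpha)
            stats_report[metric] = {
                "branch": res.branch_taken,
                "gate_test": res.gate_test,
                "gate_p": res.gate_p,
                "main_test": res.main_test,
                "main_p": res.main_p,
                "significant": res.significant,
                "posthoc": [
                    {
                        "pair": [
                            config.conditions[i].label,
                            config.conditions[j].label,
                        ],
                        "adjusted_p": p,
                    }
                    for (i, j), p in (res.posthoc or ())
                ]
                or None,
            }

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_conditions": len(config.conditions),
        "reference_condition": ref_label,
        "fit_weighting": "equal weights, flash to flash+5 s window",
    }
    return PipelineResult(
        results_table=table,
        propensities=propensities,
        ratios=ratios,
        stats=stats_report,
        provenance=provenance,
    )
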