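"""End-to-end orchestration: simulate, fit, calibrate, scale, classify, report.

`run_pipeline` executes the full analysis on synthetic data for a list of
constructs: it simulates the isochronal, envelope-of-tails and deactivation
protocol families per construct, measures activation parameters and time
constants with the tail-current toolchain, computes perturbation energies
against WT, calibrates the WT model prefactors from the WT measurements,
scales them by each mutant's observed rate-constant ratios, predicts each
mutant's isochronal V0.5 and classifies the mutants by prediction error.
Outputs are per-stage CSV tables, a machine-readable JSON summary (byte-
identical for identical configs) and a plain-text log.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import fitting
from .calibration import (
    CalibrationResult, MutantSummary, RateObservations, SCALING_OFFSETS_MV,
    calibrate_construct, classify_mutant, measure_rate_ratios,
    predict_v05_isochronal, scale_mutant_rates,
)
from .gating import build_scheme1
from .protocols import (
    DEFAULT_ENVELOPE_DURATIONS, build_deactivation_protocol,
    build_envelope_protocol, build_isochronal_protocol,
)
from .synth import CellModel, generate_mutant_library, simulate_family, write_traces

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]

#: Envelope step durations used by the pipeline; wide log spacing so the
#: rise is sampled for activation time constants from ~2 ms (very
#: depolarised steps) to ~300 ms (steps near V0.5).
PIPELINE_ENVELOPE_DURATIONS = (2.0, 4.0, 7.0, 12.0, 20.0, 35.0, 60.0,
                               100.0, 170.0, 300.0, 500.0, 850.0, 1400.0)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run."""

    constructs: list[str] = Field(default_factory=lambda: ["WT"])
    seed: int = 1
    outdir: Path = Path("herggating_run")
    noise_sd: float | None = None       # override the cell default
    isochronal_voltages: list[float] = Field(
        default_factory=lambda: list(np.arange(-120.0, 50.0 + 1e-9, 10.0)))
    envelope_voltages: list[float] = Field(
        default_factory=lambda: list(np.arange(0.0, 160.0 + 1e-9, 20.0)))
    envelope_durations: list[float] = Field(
        default_factory=lambda: list(PIPELINE_ENVELOPE_DURATIONS))
    deactivation_voltages: list[float] = Field(
        default_factory=lambda: list(np.arange(-160.0, -50.0 + 1e-9, 10.0)))
    blank_ms: float = 2.0
    readout: str = "end_of_pulse"       # isochronal prediction readout
    scaling_offsets: dict[str, float] = Field(
        default_factory=lambda: dict(SCALING_OFFSETS_MV))
    write_trace_files: bool = False

    @field_validator("constructs")
    @classmethod
    def _known_constructs(cls, v):
        library = generate_mutant_library()
        unknown = [c for c in v if c not in library]
        if unknown:
            raise ValueError(f"unknown constructs {unknown}; available: "
                             f"{sorted(library)}")
        if "WT" not in v:
            raise ValueError("the construct list must include WT (reference "
                             "for ddG0 and rate ratios)")
        return v

    @field_validator("readout")
    @classmethod
    def _known_readout(cls, v):
        if v not in ("end_of_pulse", "peak_tail"):
            raise ValueError("readout must be 'end_of_pulse' or 'peak_tail'")
        return v


def _construct_seed(seed: int, construct: str, family: str) -> int:
    return int(np.random.SeedSequence(
        [seed, abs(hash((construct, family))) % (2**31)]
    ).generate_state(1)[0] % (2**31))


def _measure_construct(label: str, config: RunConfig, log) -> dict:
    """Simulate all families for one construct and measure everything."""
    library = generate_mutant_library()
    params, cell = library[label]
    if config.noise_sd is not None:
        cell = CellModel(g_max=cell.g_max, e_rev=cell.e_rev,
                         g_leak=cell.g_leak, e_leak=cell.e_leak,
                         noise_sd=config.noise_sd,
                         temperature=cell.temperature,
                         inactivation=cell.inactivation)
    import yaml
    from .synth import _library_path
    tail_v = yaml.safe_load(_library_path().read_text())["constructs"][label] \
        .get("tail_voltage", -70.0)
    scheme = build_scheme1(params)

    # isochronal activation
    fam = build_isochronal_protocol(config.isochronal_voltages,
                                    tail_voltage=tail_v)
    traces = simulate_family(scheme, cell, fam,
                             seed=_construct_seed(config.seed, label, "iso"),
                             construct=label)
    if config.write_trace_files:
        trace_dir = config.outdir / "traces"
        trace_dir.mkdir(parents=True, exist_ok=True)
        write_traces(traces, trace_dir / f"{label}_isochronal.csv")
    sub = [fitting.leak_subtract(tr) for tr in traces]
    volts = [tr.protocol.segment("prepulse").voltage for tr in sub]
    peaks = fitting.peak_tail_family(sub, blank_ms=config.blank_ms)
    boltz = fitting.fit_boltzmann(volts, peaks)
    thermo = fitting.fit_thermo_boltzmann(volts, peaks)

    # envelope-of-tails activation taus
    activation = []
    for v in config.envelope_voltages:
        famv = build_envelope_protocol(step_voltage=v,
                                       durations=config.envelope_durations)
        traces_v = simulate_family(
            scheme, cell, famv,
            seed=_construct_seed(config.seed, label, f"env{v}"),
            construct=label)
        sub_v = [fitting.leak_subtract(tr) for tr in traces_v]
        durs = [tr.protocol.segment("step").duration for tr in sub_v]
        pk = fitting.peak_tail_family(sub_v, blank_ms=config.blank_ms)
        env = fitting.envelope_activation_tau(durs, pk)
        if not env.ill_conditioned:
            activation.append((float(v), env.tau))

    # deactivation fast components; tails near the reversal potential carry
    # no usable signal and are skipped by an amplitude filter
    famd = build_deactivation_protocol(config.deactivation_voltages)
    traces_d = simulate_family(
        scheme, cell, famd,
        seed=_construct_seed(config.seed, label, "deact"), construct=label)
    segments = []
    for tr in traces_d:
        t, y = fitting.leak_subtract(tr).segment_samples("tail")
        keep = t > config.blank_ms
        t, y = t[keep], y[keep]
        segments.append((tr.protocol.segment("tail").voltage, t, y,
                         abs(float(np.mean(y[:5]) - np.mean(y[-20:])))))
    max_amp = max(a for *_, a in segments)
    deactivation = []
    for v, t, y, amp in segments:
        if amp < 0.05 * max_amp:
            continue
        try:
            comp = fitting.deactivation_components(t, y)
        except fitting.FitError:
            continue
        deactivation.append((v, comp.tau_dominant))

    obs = RateObservations(label, tuple(activation), tuple(deactivation))
    log(f"  {label}: V0.5 {boltz.v05:.2f} mV, k {boltz.k_slope:.2f} mV, "
        f"{len(activation)} activation / {len(deactivation)} deactivation taus")
    return {"label": label, "params": params, "boltzmann": boltz,
            "thermo": thermo, "observations": obs, "tail_voltage": tail_v}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dict also written to JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        print(msg, file=sys.stderr)

    def flush_log() -> None:
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")

    measured: dict[str, dict] = {}
    stage = "simulate+fit"
    try:
        t0 = time.perf_counter()
        log(f"[{stage}] constructs: {config.constructs}")
        for label in config.constructs:
            measured[label] = _measure_construct(label, config, log)
        log(f"[{stage}] done in {time.perf_counter() - t0:.1f} s")

        stage = "ddG0"
        wt_thermo = measured["WT"]["thermo"]
        for label, m in measured.items():
            m["ddg"] = fitting.delta_delta_g(m["thermo"], wt_thermo)

        stage = "calibrate"
        t0 = time.perf_counter()
        wt = measured["WT"]
        obs = wt["observations"]
        act = dict(obs.activation)
        tau_act_target = {20.0: act[20.0]} if 20.0 in act else \
            {min(act): act[min(act)]}
        deact = dict(obs.deactivation)
        v_d = min(deact, key=lambda v: abs(v - (-130.0)))
        calib = calibrate_construct(wt["boltzmann"].v05,
                                    wt["boltzmann"].k_slope,
                                    tau_act_target, {v_d: deact[v_d]},
                                    readout=config.readout)
        log(f"[calibrate] WT prefactors {calib.params.to_dict()} "
            f"(residual V0.5 {calib.residuals['v05_mV']:+.3f} mV) in "
            f"{time.perf_counter() - t0:.1f} s")

        stage = "scale+classify"
        summaries = []
        for label in config.constructs:
            m = measured[label]
            if label == "WT":
                ratios = {k: 1.0 for k in config.scaling_offsets}
                predicted = calib.v05
            else:
                ratios = measure_rate_ratios(
                    wt["observations"], wt["boltzmann"].v05,
                    m["observations"], m["boltzmann"].v05,
                    offsets=config.scaling_offsets)
                scaled = scale_mutant_rates(calib.params, ratios)
                predicted = predict_v05_isochronal(
                    scaled, readout=config.readout,
                    tail_voltage=m["tail_voltage"])
            summary = MutantSummary(label, m["boltzmann"].v05, predicted,
                                    ratios,
                                    classify_mutant(predicted,
                                                    m["boltzmann"].v05))
            summaries.append(summary)
            log(f"  {label}: observed {summary.observed_v05:.1f} mV, "
                f"predicted {summary.predicted_v05:.1f} mV -> "
                f"{summary.classification}")

        stage = "report"
        report = write_report(summaries, measured, calib, config)
    except Exception as exc:
        log(f"[{stage}] FAILED: {exc}")
        flush_log()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    flush_log()
    return report


def _round6(x: float) -> float:
    return float(np.round(float(x), 6))


def write_report(summaries: list[MutantSummary], measured: dict,
                 calib: CalibrationResult, config: RunConfig) -> dict:
    """Write the per-construct summary CSV, machine JSON and return it."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not summaries:
        raise ValueError("at least one construct summary is required")

    rows = []
    constructs_json = {}
    for s in summaries:
        m = measured[s.construct]
        obs = m["observations"]
        act = dict(obs.activation)
        deact = dict(obs.deactivation)

        def tau_near(table, v_target):
            if not table:
                return float("nan")
            v = min(table, key=lambda vv: abs(vv - v_target))
            return table[v] if abs(v - v_target) <= 21.0 else float("nan")

        v05 = s.observed_v05
        row = {
            "construct": s.construct,
            "V05_mV": _round6(v05),
            "k_mV": _round6(m["boltzmann"].k_slope),
            "dG0_kJ_mol": _round6(m["thermo"].dG0),
            "z_g": _round6(m["thermo"].z_g),
            "ddG0_kJ_mol": _round6(m["ddg"].ddG0),
            "ddG0_gt_4p2": bool(m["ddg"].significant),
            "tau_act_V05p40_ms": _round6(tau_near(act, v05 + 40.0)),
            "tau_act_V05p180_ms": _round6(tau_near(act, v05 + 180.0)),
            "tau_deact_V05m40_ms": _round6(tau_near(deact, v05 - 40.0)),
            "tau_deact_V05m130_ms": _round6(tau_near(deact, v05 - 130.0)),
            "predicted_V05_mV": _round6(s.predicted_v05),
            "model_error_mV": _round6(s.error_mv),
            "classification": s.classification,
        }
        rows.append(row)
        constructs_json[s.construct] = dict(
            row, ratios={k: _round6(v) for k, v in sorted(s.ratios.items())})

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "summary.csv", index=False)

    report = {
        "config": json.loads(config.model_dump_json(exclude={"outdir"})),
        "wt_prefactors": {k: _round6(v)
                          for k, v in calib.params.to_dict().items()},
        "constructs": constructs_json,
    }
    (outdir / "summary.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")

    # human-readable table
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(table.to_string(index=False) + "\n")
    return report
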