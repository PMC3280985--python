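"""Synthetic two-electrode voltage-clamp current generation.

The membrane current is the Ohmic channel current plus a linear leak and
Gaussian recording noise:

    I(t) = g_max * P_open(t) * (V(t) - E_rev) + g_leak * (V(t) - E_leak) + noise

with conductances in uS, voltages in mV and currents in nA.  Gating
occupancy P_open comes from exact propagation of a chain gating scheme
through the sweep's voltage segments.  An optional fast inactivated
state attached to the open state reproduces the characteristic "hooked"
tail currents (recovery from inactivation preceding deactivation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import GatingScheme, RateLaw, build_scheme1, equilibrium_occupancy, relax_piecewise
from .params import ModelParams
from .protocols import ProtocolFamily, ProtocolSegment, SweepProtocol

__all__ = [
    "CellModel", "CurrentTrace", "simulate_current_sweep", "simulate_family",
    "generate_mutant_library", "get_construct", "write_traces", "read_traces",
    "DEFAULT_INACTIVATION",
]

#: Fast inactivation rate laws (O -> I forward, I -> O backward) used when a
#: CellModel enables the inactivated state.  Chosen so that inactivation is
#: much faster than deactivation, strongly occupied at depolarised
#: potentials (~90% at +40 mV), and recovers with a ~3-4 ms time constant
#: at -120 mV -- slower than the sampling interval but faster than
#: deactivation -- producing clearly hooked tails.
DEFAULT_INACTIVATION = (RateLaw(0.137, 0.010), RateLaw(0.041, -0.015))


@dataclass(frozen=True)
class CellModel:
    """Passive and recording properties of one synthetic oocyte."""

    g_max: float = 1.0        # uS, maximal channel conductance
    e_rev: float = -100.0     # mV, K+ reversal potential (2 mM external K+)
    g_leak: float = 0.01      # uS, linear leak conductance
    e_leak: float = 0.0       # mV, leak reversal
    noise_sd: float = 0.5     # nA, Gaussian recording noise
    temperature: float = 295.15  # K, room temperature
    inactivation: tuple[RateLaw, RateLaw] | None = None  # (O->I, I->O)

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.g_leak < 0 or self.noise_sd < 0:
            raise ValueError("g_max, g_leak and noise_sd must be >= 0")

    def with_inactivation(self) -> "CellModel":
        return replace(self, inactivation=DEFAULT_INACTIVATION)


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled current for one sweep, with its protocol and provenance."""

    dt: float                      # sampling interval, ms
    current: np.ndarray            # nA, includes the t=0 sample
    protocol: SweepProtocol
    sweep_id: int = 0
    construct: str = "WT"
    seed: int | None = None
    family_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current samples must be finite")
        n_expected = int(round(self.protocol.total_duration / self.dt)) + 1
        if len(self.current) != n_expected:
            raise ValueError(
                f"sample count {len(self.current)} does not match protocol "
                f"duration/interval (expected {n_expected})")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.current)) * self.dt

    def voltage(self) -> np.ndarray:
        """Command voltage at each sample.

        The sample on a segment boundary belongs to the segment that just
        ended (samples are taken at the end of each dt interval).
        """
        t = self.time
        v = np.empty_like(t)
        v[0] = self.protocol.segments[0].voltage
        start = 0.0
        for seg in self.protocol.segments:
            end = start + seg.duration
            mask = (t > start + 1e-12) & (t <= end + 1e-12)
            v[mask] = seg.voltage
            start = end
        return v

    def segment_samples(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(time-from-segment-start, current) for the labelled segment."""
        start, end = self.protocol.segment_window(label)
        t = self.time
        mask = (t > start + 1e-12) & (t <= end + 1e-12)
        return t[mask] - start, self.current[mask]

    def with_current(self, current: np.ndarray) -> "CurrentTrace":
        return replace(self, current=current)


def _scheme_for_cell(scheme: GatingScheme, cell: CellModel) -> GatingScheme:
    if cell.inactivation is None:
        return scheme
    fwd, bwd = cell.inactivation
    return scheme.extended("I", fwd, bwd)


def simulate_current_sweep(scheme: GatingScheme, cell: CellModel,
                           protocol: SweepProtocol, seed: int | None = None,
                           dt: float = 1.0, construct: str = "WT",
                           family_id: str = "") -> CurrentTrace:
    """Simulate one sweep; deterministic for a given seed.

    The gating occupancy starts at equilibrium for the holding potential
    and is propagated exactly through each constant-voltage segment.
    """
    sim_scheme = _scheme_for_cell(scheme, cell)
    p0 = equilibrium_occupancy(sim_scheme, protocol.holding_voltage)
    times, occ = relax_piecewise(sim_scheme, p0, protocol.as_steps(), dt=dt)
    p_open = occ @ sim_scheme.conducting_mask().astype(float)

    # voltage per sample (boundary samples belong to the ending segment)
    v = np.empty_like(times)
    v[0] = protocol.segments[0].voltage
    start = 0.0
    for seg in protocol.segments:
        end = start + seg.duration
        mask = (times > start + 1e-12) & (times <= end + 1e-12)
        v[mask] = seg.voltage
        start = end

    current = cell.g_max * p_open * (v - cell.e_rev) \
        + cell.g_leak * (v - cell.e_leak)
    if cell.noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, cell.noise_sd, size=current.shape)
    if not np.all(np.isfinite(current)):
        raise FloatingPointError("non-finite current produced by the model")
    return CurrentTrace(dt, current, protocol, protocol.sweep_id,
                        construct, seed, family_id)


def simulate_family(scheme: GatingScheme, cell: CellModel,
                    family: ProtocolFamily, seed: int | None = None,
                    dt: float = 1.0, construct: str = "WT") -> list[CurrentTrace]:
    """Simulate every sweep of a family with per-sweep derived seeds."""
    traces = []
    for sweep in family:
        sweep_seed = None
        if seed is not None:
            sweep_seed = int(np.random.SeedSequence(
                [int(seed), sweep.sweep_id]).generate_state(1)[0] % (2**31))
        traces.append(simulate_current_sweep(
            scheme, cell, sweep, seed=sweep_seed, dt=dt,
            construct=construct, family_id=family.family_id))
    return traces


# ---------------------------------------------------------------------------
# Construct fixture library


def _library_path() -> Path:
    return Path(__file__).parent / "data" / "mutant_library.yaml"


def generate_mutant_library() -> dict[str, tuple[ModelParams, CellModel]]:
    """WT plus the eleven linker mutants as (prefactors, cell) fixtures.

    Prefactor sets were calibrated once against each construct's target
    isochronal V0.5 (and, where published, kinetics) and are shipped
    frozen; see data/README.md for provenance and
    scripts/calibrate_library.py for the calibration run.
    """
    import yaml
    payload = yaml.safe_load(_library_path().read_text())
    library: dict[str, tuple[ModelParams, CellModel]] = {}
    for label, entry in payload["constructs"].items():
        params = ModelParams.from_dict(entry["params"])
        cell_kwargs = entry.get("cell", {})
        library[label] = (params, CellModel(**cell_kwargs))
    return library


def get_construct(label: str) -> tuple[ModelParams, CellModel]:
    library = generate_mutant_library()
    if label not in library:
        raise KeyError(f"unknown construct {label!r}; available: "
                       f"{sorted(library)}")
    return library[label]


# ---------------------------------------------------------------------------
# Trace IO: one CSV per sweep family plus a JSON sidecar with metadata.


def write_traces(traces: list[CurrentTrace], csv_path: str | Path) -> None:
    """Write a family of traces to CSV + JSON sidecar (lossless)."""
    csv_path = Path(csv_path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "sweep_id": tr.sweep_id,
            "time_ms": tr.time,
            "current_nA": tr.current,
        }))
    # default float formatting is the shortest repr that round-trips exactly
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    meta = {
        "format": "herggating-traces-v1",
        "sweeps": [
            {
                "sweep_id": tr.sweep_id,
                "sampling_interval_ms": tr.dt,
                "construct": tr.construct,
                "seed": tr.seed,
                "family_id": tr.family_id,
                "holding_voltage": tr.protocol.holding_voltage,
                "variable": tr.protocol.variable,
                "segments": [
                    {"voltage": s.voltage, "duration": s.duration,
                     "label": s.label}
                    for s in tr.protocol.segments
                ],
            }
            for tr in traces
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_traces(csv_path: str | Path) -> list[CurrentTrace]:
    """Read a family written by :func:`write_traces`."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        table = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # surface the parser's line information
        raise ValueError(f"{csv_path}: malformed trace CSV: {exc}") from exc
    for col in ("sweep_id", "time_ms", "current_nA"):
        if col not in table.columns:
            raise ValueError(f"{csv_path}: missing required column {col!r}")
    traces = []
    for entry in meta.get("sweeps", []):
        for key in ("sweep_id", "sampling_interval_ms", "segments"):
            if key not in entry:
                raise ValueError(f"{sidecar}: sweep entry missing field {key!r}")
        segs = tuple(ProtocolSegment(s["voltage"], s["duration"],
                                     s.get("label", ""))
                     for s in entry["segments"])
        protocol = SweepProtocol(segs, entry.get("holding_voltage", -90.0),
                                 entry.get("variable", ""), entry["sweep_id"])
        rows = table[table["sweep_id"] == entry["sweep_id"]]
        if rows.empty:
            raise ValueError(f"{csv_path}: no samples for sweep "
                             f"{entry['sweep_id']}")
        traces.append(CurrentTrace(
            float(entry["sampling_interval_ms"]),
            rows["current_nA"].to_numpy(), protocol, entry["sweep_id"],
            entry.get("construct", "WT"), entry.get("seed"),
            entry.get("family_id", "")))
    return traces
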