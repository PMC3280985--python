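"""Voltage-clamp protocol builders.

A sweep is an ordered list of constant-voltage segments.  Every sweep
starts with a short leak-estimation step (+20 mV from holding by default,
-30 mV selectable) bracketed by holding segments, so that off-line linear
leak subtraction is possible, mirroring standard two-electrode
voltage-clamp practice.  Families of sweeps vary exactly one element:
the prepulse voltage (isochronal activation), the depolarising-step
duration (envelope of tails) or the tail voltage (deactivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HOLDING_MV = -90.0
LEAK_STEP_MV = 20.0  # +20 mV from holding; -30 also used experimentally

#: Step durations (ms) for the envelope-of-tails protocol.  Spaced to
#: sample both the rise and the plateau of activation time courses with
#: time constants of tens to hundreds of ms.
DEFAULT_ENVELOPE_DURATIONS = (
    10.0, 20.0, 40.0, 70.0, 100.0, 150.0, 220.0, 320.0, 450.0, 650.0, 1000.0,
)


@dataclass(frozen=True)
class ProtocolSegment:
    voltage: float  # mV
    duration: float  # ms
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"segment duration must be > 0, got {self.duration!r}")
        if not np.isfinite(self.voltage):
            raise ValueError("segment voltage must be finite")


@dataclass(frozen=True)
class SweepProtocol:
    """One sweep: ordered segments plus bookkeeping for its family."""

    segments: tuple[ProtocolSegment, ...]
    holding_voltage: float = HOLDING_MV
    variable: str = ""  # label of the segment that varies across the family
    sweep_id: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a sweep needs at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment(self, label: str) -> ProtocolSegment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no segment labelled {label!r}; have "
                       f"{[s.label for s in self.segments]}")

    def segment_window(self, label: str) -> tuple[float, float]:
        """(start, end) time in ms of the first segment with this label."""
        t = 0.0
        for s in self.segments:
            if s.label == label:
                return t, t + s.duration
            t += s.duration
        raise KeyError(f"no segment labelled {label!r}")

    def as_steps(self) -> list[tuple[float, float]]:
        return [(s.voltage, s.duration) for s in self.segments]


@dataclass(frozen=True)
class ProtocolFamily:
    """A set of sweeps differing in exactly one element."""

    family_id: str
    kind: str  # "isochronal" | "envelope" | "deactivation"
    sweeps: tuple[SweepProtocol, ...]
    variable: str = ""

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


def _preamble(holding: float, leak_step: float) -> tuple[ProtocolSegment, ...]:
    return (
        ProtocolSegment(holding, 100.0, "hold_pre"),
        ProtocolSegment(holding + leak_step, 100.0, "leak_step"),
        ProtocolSegment(holding, 100.0, "hold"),
    )


def build_isochronal_protocol(prepulse_voltages, tail_voltage: float = -70.0,
                              holding: float = HOLDING_MV,
                              prepulse_ms: float = 4000.0,
                              tail_ms: float = 1000.0,
                              leak_step: float = LEAK_STEP_MV) -> ProtocolFamily:
    """Isochronal activation family: 4-s prepulses, tail at -70 or -120 mV.

    Each sweep: leak-estimation step, hold, the 4000-ms variable-voltage
    prepulse, then the fixed tail segment where peak tail currents report
    the open fraction reached during the prepulse.
    """
    prepulse_voltages = list(prepulse_voltages)
    if not prepulse_voltages:
        raise ValueError("prepulse_voltages must be non-empty")
    sweeps = []
    for i, v in enumerate(prepulse_voltages):
        segs = _preamble(holding, leak_step) + (
            ProtocolSegment(float(v), prepulse_ms, "prepulse"),
            ProtocolSegment(float(tail_voltage), tail_ms, "tail"),
        )
        sweeps.append(SweepProtocol(segs, holding, "prepulse", i))
    return ProtocolFamily(f"isochronal_tail{int(tail_voltage)}", "isochronal",
                          tuple(sweeps), "prepulse")


def build_envelope_protocol(step_voltage: float = 20.0,
                            durations=DEFAULT_ENVELOPE_DURATIONS,
                            tail_voltage: float = -70.0,
                            holding: float = HOLDING_MV,
                            tail_ms: float = 500.0,
                            leak_step: float = LEAK_STEP_MV) -> ProtocolFamily:
    """Envelope-of-tails family: depolarising steps of increasing duration.

    Peak tail amplitude versus step duration traces the activation time
    course at `step_voltage`.
    """
    durations = [float(d) for d in durations]
    if not durations:
        raise ValueError("durations must be non-empty")
    if any(b <= a for a, b in zip(durations, durations[1:])):
        raise ValueError("durations must be strictly increasing")
    sweeps = []
    for i, d in enumerate(durations):
        segs = _preamble(holding, leak_step) + (
            ProtocolSegment(float(step_voltage), d, "step"),
            ProtocolSegment(float(tail_voltage), tail_ms, "tail"),
        )
        sweeps.append(SweepProtocol(segs, holding, "step", i))
    return ProtocolFamily(f"envelope_{int(step_voltage)}mV", "envelope",
                          tuple(sweeps), "step")


def build_deactivation_protocol(tail_voltages,
                                conditioning_voltage: float = 40.0,
                                conditioning_ms: float = 1000.0,
                                tail_ms: float = 2000.0,
                                holding: float = HOLDING_MV,
                                leak_step: float = LEAK_STEP_MV) -> ProtocolFamily:
    """Deactivation family: fixed depolarising conditioning step, then a
    variable hyperpolarised tail where the current decay is fitted."""
    tail_voltages = list(tail_voltages)
    if not tail_voltages:
        raise ValueError("tail_voltages must be non-empty")
    sweeps = []
    for i, v in enumerate(tail_voltages):
        segs = _preamble(holding, leak_step) + (
            ProtocolSegment(float(conditioning_voltage), conditioning_ms,
                            "conditioning"),
            ProtocolSegment(float(v), tail_ms, "tail"),
        )
        sweeps.append(SweepProtocol(segs, holding, "tail", i))
    return ProtocolFamily("deactivation", "deactivation", tuple(sweeps), "tail")
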