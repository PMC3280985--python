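"""Analysis of voltage-clamp current traces.

Implements the standard tail-current workflow for slowly gating K+
channels: off-line linear leak subtraction, peak-tail measurement,
Boltzmann fits of isochronal activation curves (both the empirical
midpoint/slope form and the thermodynamic dG0/z_g form), perturbation
energies ddG0 between constructs, multi-exponential decomposition of
deactivating tails (with an optional hook component for recovery from
inactivation), envelope-of-tails activation time constants, and
exponential extrapolation of tau-voltage relations.

Sign conventions: the activation curve is the increasing sigmoid
I/Imax = 1/(1 + exp((V0.5 - V)/k)) with k > 0, so its value at V = V0.5
is exactly 0.5, and dG0 = z_g * F * V0.5 so that hyperpolarising shifts
give negative ddG0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .synth import CurrentTrace

__all__ = [
    "Constants", "FitError", "ExponentialFit", "BoltzmannFit", "ThermoFit",
    "DeltaDeltaG", "EnvelopeTau", "DeactivationComponents", "TauExtrapolation",
    "KCAL_PER_MOL_IN_KJ", "DDG_THRESHOLD_KJ_PER_MOL",
    "estimate_leak_step", "leak_subtract", "peak_tail", "peak_tail_family",
    "fit_exponential",
    "fit_boltzmann", "fit_thermo_boltzmann", "boltzmann_to_thermo",
    "thermo_to_boltzmann", "delta_delta_g", "envelope_activation_tau",
    "deactivation_components", "voltage_normalisation", "extrapolate_tau",
    "interpolate_tau",
]

#: 1 kcal/mol expressed in kJ/mol (4.184); the perturbation-energy
#: significance threshold is this value rounded to two significant figures.
KCAL_PER_MOL_IN_KJ = 4.184
DDG_THRESHOLD_KJ_PER_MOL = round(KCAL_PER_MOL_IN_KJ, 1)

TAU_BOUNDS_MS = (1.0, 1.0e4)


class FitError(RuntimeError):
    """A fit failed to converge or its preconditions were violated."""


@dataclass(frozen=True)
class Constants:
    """Physical constants for the thermodynamic Boltzmann form."""

    F: float = 96485.0   # C/mol
    R: float = 8.314     # J/(mol K)
    T: float = 295.15    # K

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError("temperature must be > 0 K")

    @property
    def RT(self) -> float:
        """J/mol."""
        return self.R * self.T

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in mV (~25.4 mV at room temperature)."""
        return 1000.0 * self.RT / self.F


@dataclass(frozen=True)
class BoltzmannFit:
    v05: float       # mV
    k_slope: float   # mV, > 0
    i_max: float
    residual_norm: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.k_slope > 0):
            raise ValueError("slope factor must be > 0")

    def value(self, v: float) -> float:
        return 1.0 / (1.0 + np.exp((self.v05 - v) / self.k_slope))


@dataclass(frozen=True)
class ThermoFit:
    dG0: float       # kJ/mol, work done at 0 mV
    z_g: float       # effective gating charges, > 0
    residual_norm: float
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.z_g > 0):
            raise ValueError("effective gating charge must be > 0")


@dataclass(frozen=True)
class ExponentialFit:
    """Sum-of-exponentials fit y(t) = offset + sum_i a_i exp(-t/tau_i)."""

    n: int
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]   # ms, strictly ascending
    offset: float
    residual_norm: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.n not in (1, 2, 3):
            raise ValueError("n components must be 1, 2 or 3")
        if len(self.amplitudes) != self.n or len(self.taus) != self.n:
            raise ValueError("amplitudes/taus must have length n")
        if any(t <= 0 for t in self.taus):
            raise ValueError("taus must be > 0")
        if any(b <= a for a, b in zip(self.taus, self.taus[1:])):
            raise ValueError("taus must be strictly ascending")

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-t / tau)
        return out


@dataclass(frozen=True)
class DeltaDeltaG:
    ddG0: float          # kJ/mol, mutant minus WT
    significant: bool    # strictly greater than the 4.2 kJ/mol threshold


@dataclass(frozen=True)
class EnvelopeTau:
    tau: float           # ms
    fit: ExponentialFit
    ill_conditioned: bool = False


@dataclass(frozen=True)
class DeactivationComponents:
    tau_fast: float
    tau_slow: float | None
    fast_fraction: float     # A_fast / (A_fast + A_slow), in [0, 1]
    hook_tau: float | None
    fit: ExponentialFit
    tau_dominant: float = float("nan")  # tau of the largest-amplitude decay


@dataclass(frozen=True)
class TauExtrapolation:
    tau: float
    extrapolated: bool    # True when target is >10 mV beyond the data
    a: float              # tau(V) = a * exp(b V)
    b: float


# ---------------------------------------------------------------------------
# Leak subtraction


def estimate_leak_step(trace: CurrentTrace) -> tuple[float, float]:
    """(dV, dI) of the leak-estimation step relative to the holding baseline.

    Uses the mean current over the second half of the 'leak_step' and
    'hold_pre' segments (the channel conductance is negligible at both
    potentials, so the difference is pure leak).
    """
    _, i_hold = trace.segment_samples("hold_pre")
    _, i_leak = trace.segment_samples("leak_step")
    v_hold = trace.protocol.segment("hold_pre").voltage
    v_leak = trace.protocol.segment("leak_step").voltage
    d_i = float(np.mean(i_leak[len(i_leak) // 2:])
                - np.mean(i_hold[len(i_hold) // 2:]))
    return v_leak - v_hold, d_i


def leak_subtract(trace: CurrentTrace,
                  leak_step: tuple[float, float] | None = None) -> CurrentTrace:
    """Subtract the linear leak estimated from the leak step.

    The leak conductance g = dI/dV anchors a line through the holding
    baseline, so a pure-leak trace maps to zero whatever the leak
    reversal potential.
    """
    if leak_step is None:
        leak_step = estimate_leak_step(trace)
    d_v, d_i = leak_step
    if d_v == 0:
        raise ValueError("leak step dV must be nonzero")
    g = d_i / d_v
    _, i_hold = trace.segment_samples("hold_pre")
    baseline = float(np.mean(i_hold[len(i_hold) // 2:]))
    v = trace.voltage()
    corrected = trace.current - (baseline
                                 + g * (v - trace.protocol.holding_voltage))
    return trace.with_current(corrected)


# ---------------------------------------------------------------------------
# Peak tails


def peak_tail(trace: CurrentTrace, blank_ms: float = 2.0,
              label: str = "tail", smooth: int = 5) -> float:
    """Signed peak tail amplitude relative to the steady final level.

    The first `blank_ms` after the step are ignored (capacitive blanking)
    and the extremum is located on a lightly smoothed copy so a single
    noisy sample cannot define the peak.  For hooked tails the extremum
    is the hook apex.
    """
    t, y = trace.segment_samples(label)
    keep = t > blank_ms + 1e-12
    t, y = t[keep], y[keep]
    if len(y) < 5:
        raise ValueError("tail segment too short after blanking")
    n_tail = max(5, len(y) // 20)
    final = float(np.mean(y[-n_tail:]))
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        ys = np.convolve(y, kernel, mode="same")
        ys[: smooth // 2] = y[: smooth // 2]
        ys[-(smooth // 2):] = y[-(smooth // 2):]
    else:
        ys = y
    idx = int(np.argmax(np.abs(ys - final)))
    return float(ys[idx] - final)


def peak_tail_family(traces: list[CurrentTrace], blank_ms: float = 2.0,
                     label: str = "tail", smooth: int = 5) -> list[float]:
    """Signed peak tail amplitudes for a whole sweep family.

    The peak position (cursor) is located once, on the sweep with the
    largest tail, and every sweep is read at that fixed position.  Tail
    kinetics are shared across a family, so a common cursor removes the
    per-sweep peak-search bias that would otherwise inflate small tails
    relative to large ones on noisy recordings.
    """
    if not traces:
        raise ValueError("empty trace family")
    processed = []
    for tr in traces:
        t, y = tr.segment_samples(label)
        keep = t > blank_ms + 1e-12
        y = y[keep]
        if len(y) < 5:
            raise ValueError("tail segment too short after blanking")
        n_tail = max(5, len(y) // 20)
        final = float(np.mean(y[-n_tail:]))
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            ys = np.convolve(y, kernel, mode="same")
            ys[: smooth // 2] = y[: smooth // 2]
            ys[-(smooth // 2):] = y[-(smooth // 2):]
        else:
            ys = y
        processed.append((ys, final))
    n = min(len(ys) for ys, _ in processed)
    devs = [np.abs(ys[:n] - final) for ys, final in processed]
    ref = int(np.argmax([d.max() for d in devs]))
    cursor = int(np.argmax(devs[ref]))
    # read each sweep as a short forward-window average of raw samples at
    # the cursor: the window's decay loss is common to the family (shared
    # tail kinetics) and cancels on normalisation, while per-sweep noise
    # is averaged down
    w = max(smooth, 1)
    out = []
    for (ys, final), tr in zip(processed, traces):
        t, y = tr.segment_samples(label)
        y = y[t > blank_ms + 1e-12]
        out.append(float(np.mean(y[cursor:cursor + w]) - final))
    return out


# ---------------------------------------------------------------------------
# Sum-of-exponentials fitting (variable projection + multi-start)


def _varpro_residual(log_taus: np.ndarray, t: np.ndarray,
                     y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    taus = np.exp(log_taus)
    design = np.column_stack([np.exp(-t[:, None] / taus[None, :]),
                              np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ coef - y, coef


def fit_exponential(t: np.ndarray, y: np.ndarray, n: int,
                    tau_bounds: tuple[float, float] = TAU_BOUNDS_MS,
                    ) -> ExponentialFit:
    """Least-squares fit of `n` decaying exponentials plus an offset.

    Uses variable projection (amplitudes and offset solved linearly for
    any trial set of taus) with multiple log-spaced tau starts, then a
    bounded nonlinear refinement of the taus.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    if len(t) < 5 * n:
        raise FitError(f"need at least {5 * n} samples for {n} components, "
                       f"got {len(t)}")
    t0 = t[0]
    ts = t - t0  # fit in local time; amplitudes refer to segment start

    lo = max(tau_bounds[0], 1e-6)
    hi = max(tau_bounds[1], 10 * lo)
    span = max(ts[-1], 10 * lo)
    grid = np.geomspace(lo, min(hi, 3 * span), 6)
    starts = [c for c in itertools.combinations(np.log(grid), n)]

    ranked = sorted(starts, key=lambda s: float(np.square(
        _varpro_residual(np.array(s), ts, y)[0]).sum()))

    candidates = []  # (cost, x, distinct)
    for start in ranked[:3]:
        result = least_squares(
            lambda lt: _varpro_residual(lt, ts, y)[0], np.array(start),
            bounds=(np.log(lo), np.log(hi)), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not result.success:
            continue
        taus = np.sort(np.exp(result.x))
        distinct = not np.any(np.diff(taus) <= 1e-3 * taus[:-1])
        candidates.append((float(result.cost), result.x, distinct))
        # a solution at numerical precision cannot be beaten materially
        if np.sqrt(2 * result.cost) \
                <= 1e-8 * max(1.0, float(np.linalg.norm(y))):
            break
    if not candidates:
        raise FitError("exponential fit did not converge from any start")
    # cost decides; among near-ties prefer distinct taus over the classic
    # collapsed pair (near-equal taus with cancelling amplitudes)
    min_cost = min(c for c, *_ in candidates)
    preferred = [c for c in candidates
                 if c[2] and c[0] <= 2.0 * min_cost + 1e-300]
    cost, x, distinct = min(preferred or candidates, key=lambda c: c[0])
    taus = np.exp(x)
    _, coef = _varpro_residual(x, ts, y)
    order = np.argsort(taus)
    taus = taus[order]
    amps = coef[:-1][order]
    offset = float(coef[-1])
    if np.any(np.diff(taus) <= 1e-9 * taus[:-1]):
        raise FitError("exponential components collapsed to equal taus; "
                       "refit with fewer components")
    residual_norm = float(np.sqrt(2 * cost))
    return ExponentialFit(n, tuple(float(a) for a in amps),
                          tuple(float(x) for x in taus), offset,
                          residual_norm)


# ---------------------------------------------------------------------------
# Activation-curve fits


def _normalise_peaks(voltages, peaks) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(voltages, dtype=float)
    p = np.asarray(peaks, dtype=float)
    if len(v) < 4:
        raise FitError("need at least 4 points spanning the transition")
    if np.ptp(p) == 0:
        raise FitError("all peak tail currents are equal; no transition")
    # one tail polarity per family, taken from the largest peak; noisy
    # near-zero points at the foot keep their sign instead of being
    # rectified (which would bias the fitted slope)
    sign = np.sign(p[np.argmax(np.abs(p))]) or 1.0
    a = sign * p
    order = np.argsort(v)
    v, a = v[order], a[order]
    return v, a / a.max()


def _check_increasing(v: np.ndarray, y: np.ndarray) -> None:
    slope = np.polyfit(v, y, 1)[0]
    if slope <= 0:
        raise FitError("peak tail currents decrease with voltage; an "
                       "activation curve must increase (check tail polarity)")


def fit_boltzmann(voltages, peaks) -> BoltzmannFit:
    """Fit I/Imax = Imax' / (1 + exp((V0.5 - V)/k)) to peak tail currents.

    Peaks are taken as magnitudes and normalised to the largest observed
    peak tail before fitting.
    """
    v, y = _normalise_peaks(voltages, peaks)
    _check_increasing(v, y)
    v05_guess = float(v[np.argmin(np.abs(y - 0.5))])

    def model(vv, v05, k, imax):
        return imax / (1.0 + np.exp((v05 - vv) / k))

    try:
        popt, _ = curve_fit(model, v, y, p0=[v05_guess, 8.0, 1.0],
                            bounds=([v.min() - 200, 0.5, 0.1],
                                    [v.max() + 200, 200.0, 10.0]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    res = model(v, *popt) - y
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]),
                        float(np.linalg.norm(res)))


def fit_thermo_boltzmann(voltages, peaks,
                         consts: Constants = Constants()) -> ThermoFit:
    """Fit the thermodynamic Boltzmann I/Imax = 1/(1+exp((dG0 - zg F E)/RT)).

    E is the membrane potential in volts and dG0 the work done at 0 mV in
    J/mol (reported in kJ/mol); equivalent to the midpoint/slope form via
    k = RT/(z_g F) and V0.5 = dG0/(z_g F).
    """
    v, y = _normalise_peaks(voltages, peaks)
    _check_increasing(v, y)
    b = fit_boltzmann(voltages, peaks)
    zg0 = consts.RT / (consts.F * b.k_slope / 1000.0)
    dg0 = zg0 * consts.F * b.v05 / 1000.0  # J/mol

    def model(vv, dG0, zg, imax):
        return imax / (1.0 + np.exp((dG0 - zg * consts.F * vv / 1000.0)
                                    / consts.RT))

    try:
        popt, _ = curve_fit(model, v, y, p0=[dg0, zg0, 1.0],
                            bounds=([-1e6, 1e-3, 0.1], [1e6, 50.0, 10.0]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"thermodynamic Boltzmann fit did not converge: {exc}"
                       ) from exc
    res = model(v, *popt) - y
    zg = float(popt[1])
    return ThermoFit(float(popt[0]) / 1000.0, zg, float(np.linalg.norm(res)),
                     degenerate=zg < 0.1)


def boltzmann_to_thermo(fit: BoltzmannFit,
                        consts: Constants = Constants()) -> ThermoFit:
    """Exact algebraic conversion (V0.5, k) -> (dG0, z_g)."""
    z_g = consts.RT / (consts.F * fit.k_slope / 1000.0)
    dg0_kj = z_g * consts.F * (fit.v05 / 1000.0) / 1000.0
    return ThermoFit(dg0_kj, z_g, fit.residual_norm, fit.converged,
                     degenerate=z_g < 0.1)


def thermo_to_boltzmann(fit: ThermoFit,
                        consts: Constants = Constants()) -> BoltzmannFit:
    """Exact algebraic conversion (dG0, z_g) -> (V0.5, k)."""
    k_mv = 1000.0 * consts.RT / (consts.F * fit.z_g)
    v05 = 1.0e6 * fit.dG0 / (fit.z_g * consts.F)
    return BoltzmannFit(v05, k_mv, 1.0, fit.residual_norm, fit.converged)


def delta_delta_g(mutant: ThermoFit, wt: ThermoFit) -> DeltaDeltaG:
    """Perturbation energy ddG0 = dG0(mutant) - dG0(WT), kJ/mol.

    The significance flag is True only for |ddG0| strictly greater than
    4.2 kJ/mol (1 kcal/mol to two significant figures).
    """
    if not (mutant.converged and wt.converged):
        raise FitError("both thermodynamic fits must have converged")
    ddg = mutant.dG0 - wt.dG0
    return DeltaDeltaG(ddg, bool(abs(ddg) > DDG_THRESHOLD_KJ_PER_MOL))


# ---------------------------------------------------------------------------
# Kinetics


def envelope_activation_tau(durations, peaks) -> EnvelopeTau:
    """Single-exponential fit to peak tail amplitude versus step duration."""
    d = np.asarray(durations, dtype=float)
    a = np.abs(np.asarray(peaks, dtype=float))
    if len(d) < 4:
        raise FitError("need at least 4 step durations")
    fit = fit_exponential(d, a, 1)
    tau = fit.taus[0]
    plateau = abs(fit.offset) if fit.offset != 0 else a.max()
    ill = (abs(fit.amplitudes[0]) < 0.02 * max(plateau, a.max())
           or tau < 0.5 * d[0])
    return EnvelopeTau(tau, fit, bool(ill))


def deactivation_components(t: np.ndarray, y: np.ndarray,
                            hook: str = "auto") -> DeactivationComponents:
    """Decompose a leak-subtracted tail into fast/slow deactivation.

    Fits a double exponential, or a triple exponential when a hook
    (rising phase from recovery of inactivation) is detected or forced
    with ``hook='always'``.  The hook component is identified by its
    amplitude sign being opposite to the decay components'.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n_tail = max(5, len(y) // 20)
    final = float(np.mean(y[-n_tail:]))
    dev = y - final
    kernel = np.ones(5) / 5
    dev_s = np.convolve(dev, kernel, mode="same")
    peak_idx = int(np.argmax(np.abs(dev_s[2:-2]))) + 2
    hooked = hook == "always" or (
        hook == "auto"
        and np.abs(dev_s[peak_idx]) > np.abs(dev_s[0]) * 1.10
        and t[peak_idx] - t[0] >= 2.0)

    def _fit(n):
        return fit_exponential(t, y, n)

    if hooked:
        fit = _fit(3)
    else:
        try:
            fit = _fit(2)
        except FitError:
            fit = _fit(1)

    decay_sign = np.sign(dev_s[peak_idx]) or 1.0
    amps = np.array(fit.amplitudes)
    taus = np.array(fit.taus)
    # a component carrying <5% of the largest amplitude is not an
    # experimentally meaningful deactivation component (it absorbs noise
    # or the numerically invisible closed-state redistribution mode)
    significant = np.abs(amps) >= 0.05 * np.abs(amps).max()
    is_decay = (np.sign(amps) == decay_sign) & significant
    hook_tau = None
    if hooked:
        opposite = (np.sign(amps) != decay_sign) & significant
        if opposite.any():
            hook_tau = float(taus[opposite][np.argmin(taus[opposite])])
    decay_taus = taus[is_decay]
    decay_amps = np.abs(amps[is_decay])
    if decay_taus.size == 0:
        raise FitError("no decaying component found in tail")
    order = np.argsort(decay_taus)
    decay_taus, decay_amps = decay_taus[order], decay_amps[order]
    tau_dom = float(decay_taus[np.argmax(decay_amps)])
    if decay_taus.size == 1:
        return DeactivationComponents(float(decay_taus[0]), None, 1.0,
                                      hook_tau, fit, tau_dom)
    tau_fast, tau_slow = float(decay_taus[0]), float(decay_taus[-1])
    frac = float(decay_amps[0] / (decay_amps[0] + decay_amps[-1]))
    return DeactivationComponents(tau_fast, tau_slow, frac, hook_tau, fit,
                                  tau_dom)


def voltage_normalisation(v: float, fit: BoltzmannFit | ThermoFit,
                          consts: Constants = Constants()
                          ) -> tuple[float, float]:
    """(V - V0.5 in mV, electrochemical driving force z_g F (V - V0.5) kJ/mol)."""
    if isinstance(fit, ThermoFit):
        b = thermo_to_boltzmann(fit, consts)
        z_g = fit.z_g
        v05 = b.v05
    else:
        z_g = consts.RT / (consts.F * fit.k_slope / 1000.0)
        v05 = fit.v05
    dv = v - v05
    dg_kj = z_g * consts.F * (dv / 1000.0) / 1000.0
    return dv, dg_kj


def extrapolate_tau(voltages, taus, target_v: float) -> TauExtrapolation:
    """Fit tau(V) = a exp(bV) and evaluate at `target_v`.

    The result is flagged as extrapolated when the target lies more than
    10 mV beyond the last measured data point.
    """
    v = np.asarray(voltages, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("time constants must be > 0")
    if len(v) < 3:
        raise FitError("need at least 3 tau-voltage points")
    b, ln_a = np.polyfit(v, np.log(tau), 1)
    a = float(np.exp(ln_a))
    value = a * np.exp(b * target_v)
    extrapolated = bool(target_v > v.max() + 10.0 or target_v < v.min() - 10.0)
    return TauExtrapolation(float(value), extrapolated, a, float(b))


def interpolate_tau(voltages, taus, target_v: float) -> TauExtrapolation:
    """Tau at `target_v`: log-linear interpolation inside the measured
    range, exponential extrapolation from the nearest 3 points outside."""
    v = np.asarray(voltages, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("time constants must be > 0")
    order = np.argsort(v)
    v, tau = v[order], tau[order]
    if v.min() <= target_v <= v.max():
        value = float(np.exp(np.interp(target_v, v, np.log(tau))))
        return TauExtrapolation(value, False, np.nan, np.nan)
    nearest = v[:3] if target_v < v.min() else v[-3:]
    nearest_tau = tau[:3] if target_v < v.min() else tau[-3:]
    result = extrapolate_tau(nearest, nearest_tau, target_v)
    beyond = target_v > v.max() + 10.0 or target_v < v.min() - 10.0
    return TauExtrapolation(result.tau, bool(beyond), result.a, result.b)
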