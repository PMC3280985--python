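# Methods

## Gating model

Channel gating is a continuous-time Markov chain on a linear sequence of
states; the shipped instance is C1 ⇌ C2 ⇌ O with exponential rate laws
k = k(0)·exp(a·V) (V in mV, rates in ms⁻¹). The voltage coefficients are
fixed structural properties of the scheme — +0.0125 and −0.025 mV⁻¹ for
the first (low-sensitivity) step, +0.055 and −0.05 mV⁻¹ for the second
(high-sensitivity) step — so a construct is fully described by the four
0-mV prefactors A1_0, B1_0, A2_0, B2_0. The total charge equivalent of
the scheme is (0.0375+0.105)·RT/F ≈ 3.6 e₀; the observed Boltzmann slope
corresponds to ~3.0 e₀ because the first step is only partially saturated
at the midpoint. Longer chains (an extra closed state, a second open
state, a terminal inactivated state) are representable, but no default
parameters are shipped for them; building them requires explicit rate
laws.

Propagation under piecewise-constant voltage uses the eigendecomposition
of the generator per segment (fallback: matrix exponentials), so results
are exact at every sample and the sampling interval `dt` affects only
where the solution is evaluated. Occupancies are renormalised against
accumulated rounding and conserve probability to 1e−9 over multi-second
protocols. A connected chain's generator is similar to a symmetric
tridiagonal matrix and therefore has simple eigenvalues; the
degenerate-spectrum warning can still fire for numerically coincident
eigenvalues (e.g. two nearly decoupled identical relaxations), in which
case the voltage is perturbed by 1e−9 mV once.

## Synthetic recordings

A sweep is simulated as I(t) = g_max·P_open(t)·(V−E_rev) +
g_leak·(V−E_leak) + Gaussian noise. Defaults describe a healthy oocyte
recording: g_max 1 µS, E_rev −100 mV (Nernst for ~2 mM external K⁺ at
room temperature), g_leak 0.01 µS with E_leak 0 mV, noise 0.5 nA,
sampling 1 ms, holding −90 mV. Every sweep carries a +20 mV
leak-estimation step from holding (−30 mV selectable) so off-line linear
leak subtraction can be performed exactly as on real data. Optional fast
inactivation (O ⇌ I; defaults: ~90% inactivated at +40 mV, recovery τ
~3–4 ms at −120 mV) produces hooked tails.

What the generator emulates: Ohmic driving force, linear leak, stationary
Gaussian noise, exact protocol timing. What it does not: series
resistance, capacitive transients, endogenous currents, rundown, cell-to-
cell variability. Tests passing on this generator therefore validate the
estimators and the analysis logic, not robustness to those artefacts.

## Measurement layer

Leak subtraction anchors a line of conductance ΔI/ΔV through the holding
baseline, so a purely linear leak maps to zero regardless of its reversal
potential. Tails are blanked for 2 ms after the step (capacitive
blanking; configurable). Peak tails are measured family-wise: the peak
position is located once on the sweep with the largest tail (lightly
smoothed), and every sweep is read as a short forward-window average of
raw samples at that fixed cursor. Tail kinetics are shared within a
family, so the window's decay loss is common mode and cancels on
normalisation, while a per-sweep peak search would inflate small tails on
noisy records and bias the fitted slope. For the same reason the
activation-curve normalisation applies one polarity sign per family
(taken from the largest peak) instead of rectifying each point.

Sum-of-exponentials fits use variable projection (amplitudes and offset
solved linearly for any trial set of time constants) with log-spaced
multi-starts and a bounded refinement of the τs (bounds 1–10⁴ ms); the
classic collapsed local minimum (a near-equal τ pair with cancelling
amplitudes, typical for sigmoidal onsets) is escaped by refining up to
three ranked starts; the lowest-cost solution wins, with distinct-τ
solutions preferred among near-ties. Component count
is chosen by the caller, except that deactivation tails switch from a
double to a triple exponential when a hook (rising phase) is detected.
Fitted components carrying <5% of the largest amplitude are not treated
as deactivation components: in a clean three-state chain the
closed-state redistribution mode is present in the open probability only
at the 10⁻⁴ level, and on noisy records such minor components absorb
noise. The "dominant" component (largest amplitude) is what enters
rate–voltage observations; at strongly negative voltages it coincides
with the fast component.

Boltzmann fits use the increasing sigmoid I/I_max = 1/(1+exp((V₀.₅−V)/k)),
fixed by two testable identities: the curve value at V₀.₅ is 0.5, and a
hyperpolarising shift gives negative ΔΔG⁰ at positive z_g. The
thermodynamic form interconverts exactly via k = RT/(z_g F) and
V₀.₅ = ΔG⁰/(z_g F); constants F = 96485 C·mol⁻¹, R = 8.314 J·mol⁻¹·K⁻¹,
T = 295.15 K. The ΔΔG⁰ significance threshold is 4.2 kJ·mol⁻¹
(1 kcal·mol⁻¹ to two significant figures), strict inequality. τ(V)
extrapolation fits a·exp(bV) and flags any target more than 10 mV beyond
the measured range. Deactivation tails whose amplitude is below 5% of the
family maximum are discarded (tail voltages near E_rev carry no driving
force).

## Wild-type calibration

The four prefactors are fitted by weighted least squares so that the
model simultaneously reproduces the 4-s isochronal activation curve
(summarised by its fitted V₀.₅ and slope) and observed activation/
deactivation time constants, all computed with the same estimators used
on traces (for speed, the objective evaluates them analytically from the
eigenmodes, which matches the trace estimators to numerical precision on
noiseless model output). The objective has distinct basins depending on
the first step's equilibrium saturation at V₀.₅; three heuristic starts
at saturation levels K1(V₀.₅) ∈ {0.7, 2, 8} are tried and the best kept.
Residual weights default to near-exact targets (0.1 mV, 0.5% τ) for
reference calibration and should be set to the observation uncertainties
when calibrating noisy data.

Default WT targets: isochronal V₀.₅ −23.1 mV, slope 8.4 mV, envelope
activation τ 74 ms at +20 mV — and a fourth constraint is required to pin
four parameters. No reference value exists for WT fast deactivation at
−130 mV, and the scheme's exponential laws tie that quantity tightly to
the other three targets (feasible values top out near ~5 ms); the fourth
target is therefore set to the scheme-consistent 4.8 ms. The calibration
reproduces all four targets to machine precision, and the resulting model
independently shows the expected limiting behaviour: above V₀.₅+120 mV
the slope of ln(1/τ_act) flattens to the first step's 0.0125 mV⁻¹, and at
−130 mV the fast component carries ≈100% of the deactivation amplitude.

The A548V fixture is calibrated to its reference V₀.₅ (−56.8 mV, tails at
−120 mV) and envelope τ (37 ms at +20 mV) with the slope held at the WT
value. Its reported extrapolated fast deactivation τ at −130 mV (8.2 ms)
is not jointly reachable with those targets under this scheme — consistent
with this construct being one the rate-scaling model fails on — so the
deactivation target is the scheme-consistent ~80 ms. Other mutant
fixtures are derived from WT by a symmetric second-step scaling
(A2·√s, B2/√s) root-found on the simulated isochronal V₀.₅; constructs for
which only "small shifts" are reported use synthetic targets (see
data/README.md).

## Identifiability

B1_0 (the k₋₁ prefactor) is intrinsically the softest parameter: in a
chain where k₋₂ has twice k₋₁'s voltage sensitivity, the open-probability
decay at measurable negative voltages proceeds through k₋₂-dominated
modes and k₋₁ never appears in tail currents with measurable amplitude.
B1_0 is constrained only through the activation curve's slope (via the
first step's saturation), whose sensitivity is weak: a Fisher-information
analysis at the WT parameters, with 5% noise on observed τs and 1% on
curve points, gives 1-σ relative uncertainties of roughly 3% (A1_0), 15%
(B1_0), 5% (A2_0) and 2% (B2_0). Recovery studies match this: A1_0, A2_0
and B2_0 are recovered with median errors well under 5%, B1_0 around
10%. Conclusions that depend on k₋₁ individually should not be drawn
from tail-current data under this scheme.

The mutant-scaling procedure measures rate ratios at voltages matched
relative to each construct's own V₀.₅. This normalisation means the
procedure recovers kinetic perturbations and first-step changes well
(closed-loop prediction error <2 mV), but largely cancels pure
equilibrium shifts of the high-sensitivity step: a mutant that only
shifts V₀.₅ produces near-unity ratios and is "predicted" to sit at the
WT midpoint. Large prediction errors therefore flag mutants whose
steady-state shift is not explained by their measured rate changes —
which is precisely how the classification is meant to read.

## Problem sizes and study designs

Isochronal families use 18 sweeps (−120..+50 mV, 10-mV steps, 4-s
prepulse); envelope families 11 durations (10–1000 ms) at the default
+20 mV (a wider 13-duration grid, 2–1400 ms, in the pipeline, which also
scans envelope voltages 0..+160 mV and deactivation tails −160..−50 mV).
The Boltzmann recovery study runs 100 seeds at trace SNR 20 (noise sd =
largest peak tail / 20); the calibration recovery study runs 50 seeds
with 5% τ noise and 1% curve noise, weighting residuals by those
uncertainties. The acceptance script runs all measurements on noiseless
traces, as the quantities it reports are deterministic properties of the
calibrated model.

## Known limitations

- The three-state scheme has no inactivation unless explicitly enabled,
  no sigmoidal delay beyond one closed-closed step, and no temperature
  dependence.
- k₋₁ is weakly identified from tail currents (above).
- The envelope single-exponential τ is the experimental estimator, not an
  eigenvalue: at intermediate voltages it deviates from the slow
  relaxation time by up to ~20% because it absorbs the sigmoidal onset.
  The calibration deliberately targets the estimator, not the eigenvalue.
- Classification thresholds (10/25 mV) are conventions; values in
  20–25 mV are labelled intermediate.
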