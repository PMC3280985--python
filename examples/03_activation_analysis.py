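"""Tail-current analysis: leak subtraction, Boltzmann fits, perturbation
energy of a mutant against wild type.

Simulates isochronal families for WT and the A548V fixture, measures peak
tails, fits both the midpoint/slope and the thermodynamic Boltzmann
forms, and computes the mutant's ddG0 with its 4.2 kJ/mol significance
flag.
"""

import numpy as np

from herggating import (CellModel, build_scheme1, delta_delta_g,
                        fit_boltzmann, fit_thermo_boltzmann, get_construct,
                        leak_subtract, simulate_family)
from herggating.fitting import peak_tail_family
from herggating.protocols import build_isochronal_protocol


def measure(label, tail_voltage, seed):
    params, cell = get_construct(label)
    family = build_isochronal_protocol(np.arange(-120, 51, 10),
                                       tail_voltage=tail_voltage)
    traces = [leak_subtract(tr) for tr in
              simulate_family(build_scheme1(params), cell, family, seed=seed)]
    volts = [tr.protocol.segment("prepulse").voltage for tr in traces]
    peaks = peak_tail_family(traces)
    return fit_boltzmann(volts, peaks), fit_thermo_boltzmann(volts, peaks)


wt_b, wt_t = measure("WT", -70.0, seed=1)
mut_b, mut_t = measure("A548V", -120.0, seed=2)

print(f"WT    : V0.5 = {wt_b.v05:6.1f} mV, k = {wt_b.k_slope:.1f} mV, "
      f"dG0 = {wt_t.dG0:6.2f} kJ/mol, z_g = {wt_t.z_g:.2f}")
print(f"A548V : V0.5 = {mut_b.v05:6.1f} mV, k = {mut_b.k_slope:.1f} mV, "
      f"dG0 = {mut_t.dG0:6.2f} kJ/mol, z_g = {mut_t.z_g:.2f}")

d = delta_delta_g(mut_t, wt_t)
print(f"ddG0(A548V - WT) = {d.ddG0:.2f} kJ/mol; "
      f"|ddG0| > 4.2 kJ/mol: {d.significant}")
# the ~ -34 mV hyperpolarising shift corresponds to ~ -10 kJ/mol of
# stabilisation of the open state relative to WT -- well past the
# 1 kcal/mol (4.2 kJ/mol) threshold for a meaningful perturbation.
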