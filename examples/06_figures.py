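"""Standard figures: activation curves with Boltzmann fits, and
rate-voltage plots before/after V0.5 normalisation.

Writes activation_curves.png and rate_voltage.png to the current
directory.
"""

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from herggating import (CellModel, build_scheme1, fit_boltzmann,
                        get_construct, leak_subtract, simulate_family)
from herggating.calibration import model_observed_rates
from herggating.fitting import peak_tail_family
from herggating.plots import plot_activation_curves, plot_rate_voltage
from herggating.protocols import build_isochronal_protocol

curves = {}
v05 = {}
for label, tail in (("WT", -70.0), ("A548V", -120.0)):
    params, cell = get_construct(label)
    family = build_isochronal_protocol(np.arange(-120, 51, 10),
                                       tail_voltage=tail)
    traces = [leak_subtract(tr) for tr in
              simulate_family(build_scheme1(params), cell, family, seed=3)]
    volts = np.array([tr.protocol.segment("prepulse").voltage
                      for tr in traces])
    peaks = np.abs(peak_tail_family(traces))
    fit = fit_boltzmann(volts, peaks)
    curves[label] = (volts, peaks / peaks.max(), fit)
    v05[label] = fit.v05

ax = plot_activation_curves(curves)
ax.figure.savefig("activation_curves.png", dpi=120)
print("wrote activation_curves.png "
      f"(V0.5: { {k: round(v, 1) for k, v in v05.items()} })")

observations = {}
for label in ("WT", "A548V"):
    params, _ = get_construct(label)
    obs = model_observed_rates(params, np.arange(0.0, 161.0, 20.0),
                               np.arange(-160.0, -49.0, 10.0))
    observations[label] = list(obs.activation) + list(obs.deactivation)

fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
plot_rate_voltage(observations, ax=axes[0])
plot_rate_voltage(observations, ax=axes[1], normalise_v05=v05)
fig.tight_layout()
fig.savefig("rate_voltage.png", dpi=120)
print("wrote rate_voltage.png (absolute V, and V - V0.5 normalised: after "
      "normalisation the A548V activation limb nearly superimposes on WT)")
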