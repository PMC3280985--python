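"""Small matplotlib helpers for the standard figures of this analysis:
normalised activation curves with their Boltzmann fits, and rate-voltage
(1/tau) plots for activation/deactivation kinetics."""

from __future__ import annotations

import numpy as np

from .fitting import BoltzmannFit


def plot_activation_curves(curves: dict, ax=None):
    """Normalised peak tails vs voltage with Boltzmann fits.

    `curves` maps a label to (voltages, normalised peaks, BoltzmannFit or
    None).
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for label, (v, y, fit) in curves.items():
        v = np.asarray(v, dtype=float)
        pts = ax.plot(v, y, "o", label=label)
        if isinstance(fit, BoltzmannFit):
            grid = np.linspace(v.min(), v.max(), 200)
            ax.plot(grid, fit.i_max * fit.value(grid), "-",
                    color=pts[0].get_color())
    ax.set_xlabel("prepulse voltage (mV)")
    ax.set_ylabel("normalised peak tail current")
    ax.legend(frameon=False)
    return ax


def plot_rate_voltage(observations: dict, ax=None, normalise_v05=None):
    """Observed rate constants (1/tau, ms^-1) against voltage on a log axis.

    `observations` maps a label to an iterable of (voltage mV, tau ms)
    pairs; `normalise_v05` maps the same labels to V0.5 values to plot
    against V - V0.5 instead of absolute voltage.
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for label, points in observations.items():
        v = np.array([p[0] for p in points], dtype=float)
        rate = 1.0 / np.array([p[1] for p in points], dtype=float)
        if normalise_v05 is not None:
            v = v - normalise_v05[label]
        order = np.argsort(v)
        ax.semilogy(v[order], rate[order], "o-", label=label)
    ax.set_xlabel("V - V0.5 (mV)" if normalise_v05 is not None
                  else "voltage (mV)")
    ax.set_ylabel("rate constant (ms$^{-1}$)")
    ax.legend(frameon=False)
    return ax
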