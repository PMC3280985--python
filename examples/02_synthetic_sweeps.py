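"""Synthetic two-electrode voltage-clamp sweeps, with and without the
fast inactivated state that produces hooked tail currents.

Simulates an isochronal activation family for the wild-type model, writes
it to CSV (+ JSON sidecar), and contrasts a plain deactivating tail with
the rising-then-falling hook seen when recovery from inactivation is
faster than deactivation.
"""

import numpy as np

from herggating import (CellModel, build_scheme1, simulate_family,
                        write_traces)
from herggating.protocols import (build_deactivation_protocol,
                                  build_isochronal_protocol)

scheme = build_scheme1()
cell = CellModel()  # 1 uS, E_rev -100 mV, linear leak, 0.5 nA noise

family = build_isochronal_protocol(np.arange(-120, 51, 10), tail_voltage=-70)
traces = simulate_family(scheme, cell, family, seed=1, construct="WT")
write_traces(traces, "wt_isochronal.csv")
print(f"wrote {len(traces)} sweeps to wt_isochronal.csv "
      "(sweep_id,time_ms,current_nA + JSON sidecar)")

tail = build_deactivation_protocol([-120.0])
plain = simulate_family(scheme, CellModel(noise_sd=0), tail)[0]
hooked = simulate_family(scheme, CellModel(noise_sd=0).with_inactivation(),
                         tail)[0]
for label, tr in (("plain", plain), ("hooked", hooked)):
    t, y = tr.segment_samples("tail")
    apex = int(np.argmax(np.abs(y - y[-1])))
    print(f"{label:6s} tail at -120 mV: first sample {y[0]:7.2f} nA, "
          f"extremum {y[apex]:7.2f} nA at t = {t[apex]:.0f} ms")
# the plain tail is largest immediately and decays; the hooked tail first
# grows (channels recovering from inactivation re-open) and peaks a few ms
# after the step, as in recordings of hERG currents.
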