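# Fixture library provenance

`mutant_library.yaml` ships frozen prefactor sets (`A1_0`, `B1_0`, `A2_0`,
`B2_0`, ms^-1 at 0 mV) for WT hERG and the eleven S4-S5 linker constructs,
calibrated once by `scripts/calibrate_library.py` so that each construct's
simulated 4-s isochronal activation curve reproduces its target V0.5.

Target values marked `provenance: published` are reported two-electrode
voltage-clamp measurements of hERG channels expressed in *Xenopus* oocytes:

| construct | V0.5 (mV) | other calibration targets |
|-----------|-----------|---------------------------|
| WT        | -23.1     | slope 8.4 mV; envelope activation tau 74 ms at +20 mV |
| S543A     | -48.0     | |
| G546A     | -63.8     | |
| A548V     | -56.8     | envelope activation tau 37 ms at +20 mV; slope held at 8.4 mV |
| L550A     | -42.0     | |

WT's fast deactivation target (4.8 ms at -130 mV) is not a published value:
it is the value consistent with the three-state scheme and the three
published WT constraints (see `docs/methods.md`).

Entries marked `provenance: synthetic` (D540A, R541A, Y542A, E544A, Y545A,
A547V, V549A) are stand-ins: only "small depolarising/hyperpolarising
shifts" are reported for these constructs, so their target V0.5 values are
plausible small shifts chosen by this package, not measurements.

`random_coil_ha.csv` holds random-coil Halpha chemical shifts (ppm) in the
style of Wishart, Bigam, Holm, Hodges & Sykes (1995), *J. Biomol. NMR* 5,
67-81, used as the reference for chemical-shift-index calculations.
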