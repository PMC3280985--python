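"""Chemical shift index (CSI) secondary-structure calls from Halpha shifts.

CSI is the observed Halpha chemical shift minus the residue's random-coil
reference value.  Sustained negative deviations mark alpha-helix: a
residue is called 'helix' when its CSI is below -0.1 ppm and it belongs
to a run of at least four consecutive such residues (a single
sub-threshold residue is not a helix); everything else is 'coil'.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

__all__ = ["ShiftRecord", "load_random_coil_table", "compute_csi",
           "classify_secondary_structure", "HELIX_THRESHOLD_PPM",
           "MIN_HELIX_RUN"]

HELIX_THRESHOLD_PPM = -0.1
MIN_HELIX_RUN = 4


@dataclass(frozen=True)
class ShiftRecord:
    residue_index: int
    amino_acid: str  # one-letter code
    ha_shift: float  # ppm

    def __post_init__(self) -> None:
        if not (0.0 <= self.ha_shift <= 12.0):
            raise ValueError(f"Halpha shift {self.ha_shift} ppm outside 0-12")
        if len(self.amino_acid) != 1:
            raise ValueError("amino_acid must be a one-letter code")


def load_random_coil_table(path: str | Path | None = None) -> dict[str, float]:
    """Random-coil Halpha reference shifts (ppm) by one-letter code.

    Defaults to the Wishart-style table shipped with the package (see
    data/README.md for the citation).
    """
    if path is None:
        path = Path(__file__).parent / "data" / "random_coil_ha.csv"
    table = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["one_letter"].strip()] = float(row["ha_ppm"])
    return table


def _sorted_unique(records: list[ShiftRecord]) -> list[ShiftRecord]:
    indices = [r.residue_index for r in records]
    if len(set(indices)) != len(indices):
        raise ValueError("residue indices must be unique")
    return sorted(records, key=lambda r: r.residue_index)


def compute_csi(records: list[ShiftRecord],
                reference: dict[str, float] | None = None
                ) -> list[tuple[int, float]]:
    """Per-residue CSI = observed - random-coil reference, in ppm."""
    if reference is None:
        reference = load_random_coil_table()
    out = []
    for rec in _sorted_unique(records):
        if rec.amino_acid not in reference:
            raise KeyError(f"residue type {rec.amino_acid!r} (index "
                           f"{rec.residue_index}) missing from the "
                           "random-coil reference table")
        out.append((rec.residue_index, rec.ha_shift - reference[rec.amino_acid]))
    return out


def classify_secondary_structure(csi_series: list[tuple[int, float]]
                                 ) -> list[tuple[int, str]]:
    """Label each residue 'helix' or 'coil' by the run-length CSI rule."""
    labels = []
    below = [csi < HELIX_THRESHOLD_PPM for _, csi in csi_series]
    n = len(below)
    helix = [False] * n
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j] and (j == i or
                    csi_series[j][0] == csi_series[j - 1][0] + 1):
                j += 1
            if j - i >= MIN_HELIX_RUN:
                for kk in range(i, j):
                    helix[kk] = True
            i = j
        else:
            i += 1
    for (idx, _), is_helix in zip(csi_series, helix):
        labels.append((idx, "helix" if is_helix else "coil"))
    return labels
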