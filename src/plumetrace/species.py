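"""The CHCA-related ion species seen in the matrix-only MALDI spectrum.

CHCA (alpha-cyano-4-hydroxycinnamic acid, C10H7NO3) is a standard MALDI
matrix; a matrix-only dried-droplet sample yields the protonated monomer
(m/z 190), the proton-bound dimer (m/z 379), the sodium adduct (m/z 212) and
the water-loss ion (m/z 172).  Masses are monoisotopic; nominal m/z is kept
for labels only (the kinematic difference is < 0.05%).
"""

from __future__ import annotations

import csv
from importlib import resources

from .kinematics import IonSpecies

__all__ = ["load_species_table", "get_species", "MONOMER", "DIMER"]


def load_species_table() -> dict[str, IonSpecies]:
    """Load the packaged species table as ``{label: IonSpecies}``."""
    table: dict[str, IonSpecies] = {}
    ref = resources.files("plumetrace").joinpath("data/species.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["label"]] = IonSpecies(
                label=row["label"],
                mass_u=float(row["mass_u"]),
                charge=int(row["charge"]),
                nominal_mz=int(row["nominal_mz"]),
            )
    return table


_TABLE: dict[str, IonSpecies] | None = None


def get_species(label: str) -> IonSpecies:
    """Look up a species by label, e.g. ``"(CHCA)H+"``."""
    global _TABLE
    if _TABLE is None:
        _TABLE = load_species_table()
    try:
        return _TABLE[label]
    except KeyError:
        raise KeyError(
            f"unknown species {label!r}; known: {sorted(_TABLE)}"
        ) from None


MONOMER = IonSpecies("(CHCA)H+", 190.0499, 1, 190)
DIMER = IonSpecies("(CHCA)2H+", 379.0925, 1, 379)
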