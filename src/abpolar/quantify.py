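"""Western-blot band quantities to intracellular molar concentrations.

The total Rho-GTPase concentrations used as model parameters were obtained
by comparing immunoblot band intensities against a loaded control protein
of known mass, dividing the implied mass over the number of cells in the
lysate, converting to molecules via the molecular weight and Avogadro's
number, and dividing by the volume of a sphere-approximated cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

__all__ = ["BlotSample", "blot_to_concentration", "quantify_table"]


@dataclass(frozen=True)
class BlotSample:
    """One quantified western-blot band.

    band_ratio: sample-band / control-band intensity (dimensionless).
    control_mass_pg: mass of the loaded control protein (pg).
    lysate_fraction_loaded: fraction of the total lysate loaded on the gel.
    cells_in_lysate: number of cells the total lysate represents
        (default 1.5 million, a confluent MDCK culture).
    molecular_weight_kDa: protein molecular weight (small GTPases ~21 kDa).
    cell_diameter_um: diameter of the sphere-approximated cell (10 um).
    """

    band_ratio: float
    control_mass_pg: float
    lysate_fraction_loaded: float = 1.0
    cells_in_lysate: float = 1.5e6
    molecular_weight_kDa: float = 21.0
    cell_diameter_um: float = 10.0

    def __post_init__(self) -> None:
        if self.band_ratio < 0:
            raise ValueError("band_ratio must be nonnegative")
        for name in ("control_mass_pg", "lysate_fraction_loaded",
                     "cells_in_lysate", "molecular_weight_kDa",
                     "cell_diameter_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def blot_to_concentration(sample: BlotSample) -> float:
    """Total intracellular concentration (uM) implied by a blot band.

    mass per cell = band_ratio * control_mass / lysate_fraction / n_cells;
    molecules per cell = mass / MW * N_A; concentration = molecules /
    (N_A * cell volume).  Linear in band_ratio; scales with diameter^-3.
    """
    mass_pg = (sample.band_ratio * sample.control_mass_pg
               / sample.lysate_fraction_loaded / sample.cells_in_lysate)
    grams = mass_pg * 1e-12
    mol_per_cell = grams / (sample.molecular_weight_kDa * 1e3)  # kDa -> g/mol
    volume_um3 = np.pi / 6.0 * sample.cell_diameter_um ** 3
    volume_l = volume_um3 * 1e-15
    molar = mol_per_cell / volume_l
    return molar * 1e6  # M -> uM


def quantify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the blot conversion to a table with one row per band.

    Requires columns matching the BlotSample field names minus the ``_pg``
    / ``_kDa`` / ``_um`` suffix conventions: ``protein``, ``band_ratio``,
    ``control_mass_pg`` and optionally the remaining fields.  Returns the
    table with a ``concentration_uM`` column appended.
    """
    optional = ("lysate_fraction_loaded", "cells_in_lysate",
                "molecular_weight_kDa", "cell_diameter_um")
    out = table.copy()
    conc = []
    for _, row in table.iterrows():
        kwargs = {k: row[k] for k in optional if k in table.columns}
        conc.append(blot_to_concentration(BlotSample(
            band_ratio=row["band_ratio"],
            control_mass_pg=row["control_mass_pg"], **kwargs)))
    out["concentration_uM"] = conc
    return out
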