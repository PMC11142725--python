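"""Concentration state of the twelve species on the spatial grid."""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .parameters import ModelParameters

__all__ = ["SpeciesState", "SPECIES", "OUTPUT_SPECIES", "FAMILIES"]

#: canonical species order used in the stacked (12, n_nodes) array layout
SPECIES = (
    "I_a", "I_i",
    "C_a", "C_i",
    "R_a", "R_i",
    "rho_a", "rho_i",
    "P_C", "P_un",
    "S_C", "S_un",
)

#: the six model outputs evaluated for polarization
OUTPUT_SPECIES = ("I_a", "R_a", "rho_a", "C_a", "P_C", "S_C")

#: conserved families: (active/bound field, inactive/unbound field, total attr)
FAMILIES = (
    ("I_a", "I_i", "I_tot"),
    ("C_a", "C_i", "C_tot"),
    ("R_a", "R_i", "R_tot"),
    ("rho_a", "rho_i", "rho_tot"),
    ("P_C", "P_un", "P_tot"),
    ("S_C", "S_un", "S_tot"),
)


@dataclass
class SpeciesState:
    """Concentration fields (uM) of all twelve species over the grid nodes.

    Each protein family is split into two fractions (active/inactive for
    integrins and GTPases, bound/unbound for the polarity complexes) whose
    per-node sum equals the family total at t=0 and whose spatially summed
    total is conserved by the unperturbed dynamics.
    """

    I_a: np.ndarray
    I_i: np.ndarray
    C_a: np.ndarray
    C_i: np.ndarray
    R_a: np.ndarray
    R_i: np.ndarray
    rho_a: np.ndarray
    rho_i: np.ndarray
    P_C: np.ndarray
    P_un: np.ndarray
    S_C: np.ndarray
    S_un: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.I_a)
        for f in fields(self):
            arr = np.asarray(getattr(self, f.name), dtype=float)
            if arr.ndim != 1 or len(arr) != n:
                raise ValueError(f"field {f.name} must be 1D of length {n}")
            object.__setattr__(self, f.name, arr)

    @property
    def n_nodes(self) -> int:
        return len(self.I_a)

    def as_array(self) -> np.ndarray:
        """Stack the fields into a (12, n_nodes) array in SPECIES order."""
        return np.stack([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SpeciesState":
        if arr.shape[0] != len(SPECIES):
            raise ValueError(f"expected {len(SPECIES)} rows, got {arr.shape[0]}")
        return cls(**{s: arr[i].copy() for i, s in enumerate(SPECIES)})

    def copy(self) -> "SpeciesState":
        return SpeciesState.from_array(self.as_array())

    def mirror(self) -> "SpeciesState":
        """Spatially flipped state (node i <-> node N-i)."""
        return SpeciesState(**{s: getattr(self, s)[::-1].copy() for s in SPECIES})

    def family_totals(self) -> dict[str, float]:
        """Spatially summed total per conserved family (uM, node-summed)."""
        return {tot: float(getattr(self, a).sum() + getattr(self, b).sum())
                for a, b, tot in FAMILIES}

    def validate(self, params: ModelParameters, atol: float = 1e-8) -> None:
        """Check nonnegativity and per-node family sums against the totals."""
        for s in SPECIES:
            if np.min(getattr(self, s)) < -atol:
                raise ValueError(f"negative concentration in {s}")
        for a, b, tot in FAMILIES:
            target = getattr(params, tot)
            per_node = getattr(self, a) + getattr(self, b)
            if not np.allclose(per_node, target, atol=1e-6 * max(target, 1.0)):
                raise ValueError(f"family {tot}: per-node sum deviates from total")
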