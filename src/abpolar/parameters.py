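"""Model parameters and spatial grid for the 1D polarization model.

The model tracks six conserved protein families along the apical-basal axis
of a renal epithelial cell: integrins (active/inactive), the Rho-GTPases
Cdc42, Rac and Rho (active/inactive), and the Par and Scribble polarity
complexes (bound/unbound).  All concentrations are in uM, rates in 1/s or
uM/s, diffusion coefficients in um^2/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = ["ModelParameters", "GridSpec"]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, totals and diffusion coefficients of the model.

    Defaults are the baseline parameterisation: total GTPase
    concentrations measured by quantitative immunoblotting of MDCK lysates,
    kinetic constants adapted from earlier Rho-GTPase crosstalk models, and
    polarity-complex binding kinetics from the Par-complex literature.
    """

    # Rho-GTPase totals (uM)
    C_tot: float = 4.4
    R_tot: float = 2.4
    rho_tot: float = 4.0
    # baseline activation input rates (uM/s)
    I_C: float = 0.5
    I_R: float = 0.5
    I_rho: float = 3.3
    # decay rates of the active GTPases (1/s)
    delta_C: float = 1.0
    delta_R: float = 1.0
    delta_rho: float = 1.0
    # Hill inhibition constants (uM): Rac-on-Rho, Rho-on-Rac, Par-on-Rac
    beta_R: float = 1.5
    beta_rho: float = 0.7
    beta_PR: float = 2.0
    # Cdc42-dependent Par activation and Rho-dependent Cdc42 activation (1/s)
    alpha_C: float = 2.5
    alpha_rho: float = 2.5
    # Hill coefficient (dimensionless, positive integer)
    n_hill: int = 4
    # GTPase diffusion: membrane-bound active, cytosolic inactive (um^2/s)
    D_act: float = 0.1
    D_inact: float = 10.0
    # polarity complexes (uM, uM/s, 1/s)
    P_tot: float = 1.6
    S_tot: float = 1.6
    k_on_P: float = 0.5
    k_on_S: float = 4.0
    k_off_P: float = 2.0
    k_off_S: float = 2.0
    beta_SP: float = 0.2
    beta_PS: float = 0.2
    # polarity-complex diffusion (um^2/s)
    D_PC: float = 0.2
    D_SC: float = 0.2
    D_Pun: float = 2.0
    D_Sun: float = 2.0
    # integrins
    I_tot: float = 30.0
    I_I: float = 10.0
    delta_I: float = 1.0
    alpha_I: float = 1.5
    D_Ii: float = 10.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "n_hill":
                if not isinstance(v, int) or isinstance(v, bool) or v < 1:
                    raise ValueError("n_hill must be a positive integer")
            elif not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def max_diffusion(self) -> float:
        return max(self.D_act, self.D_inact, self.D_PC, self.D_SC,
                   self.D_Pun, self.D_Sun, self.D_Ii)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GridSpec:
    """1D finite-difference grid along the basal (x=0) to apical (x=L) axis.

    The default 30 subdomains (31 nodes) over a 10 um cell with dt = 0.005 s
    are the mesh- and time-step-converged settings of the baseline model.
    """

    L: float = 10.0
    n_sub: int = 30
    dt: float = 0.005

    def __post_init__(self) -> None:
        if self.n_sub < 2:
            raise ValueError("n_sub must be >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.L > 0:
            raise ValueError("L must be positive")

    @property
    def dx(self) -> float:
        return self.L / self.n_sub

    @property
    def n_nodes(self) -> int:
        return self.n_sub + 1

    def check_stability(self, params: ModelParameters) -> None:
        """Raise if the explicit-Euler diffusion stability bound is violated.

        The forward-Euler scheme requires dt <= dx^2 / (2 * D_max).
        """
        bound = self.dx ** 2 / (2.0 * params.max_diffusion)
        if self.dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} violates the diffusion stability bound "
                f"dx^2/(2*D_max)={bound:.6g} s"
            )
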