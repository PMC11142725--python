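"""Local (non-diffusive) reaction kinetics of the polarization network.

The network couples integrin outside-in signaling to the Rho-GTPase
crosstalk and the mutually inhibitory Par/Scribble polarity complexes:

* active integrins (basal, ECM-bound) activate Rac,
* Rac and Rho mutually inhibit each other (Hill inhibition),
* Rho activates Cdc42, Cdc42 promotes Par-complex binding,
* Par and Scribble inhibit each other's binding, and Par inhibits Rac.

Every family switches between two fractions with exactly antisymmetric
source terms, so reactions conserve each family's total concentration.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters
from .state import SpeciesState

__all__ = ["hill_inhibition", "combined_rac_inhibition", "reaction_rates"]

# row indices of the stacked (12, n_nodes) state array, in state.SPECIES order
IA, II, CA, CI, RA, RI, RHOA, RHOI, PC, PUN, SC, SUN = range(12)


def hill_inhibition(value, beta: float, n: int):
    """Hill inhibition factor 1 / (1 + (value/beta)^n).

    Returns 1 for zero input, 1/2 at value == beta, and decreases
    monotonically toward 0 as ``value`` grows; steepness is set by the
    Hill coefficient ``n``.
    """
    if not beta > 0:
        raise ValueError("beta must be strictly positive")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError("Hill coefficient n must be an integer >= 1")
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("concentration must be nonnegative")
    out = 1.0 / (1.0 + (value / beta) ** int(n))
    return float(out) if out.ndim == 0 else out


def combined_rac_inhibition(rho_a, P_C, params: ModelParameters):
    """Joint inhibition of Rac activation by active Rho and the Par complex.

    Factor 1 / (1 + (rho_a/beta_rho)^n + (P_C/beta_PR)^n): the two
    inhibitors act additively inside a single Hill-type denominator.
    """
    rho_a = np.asarray(rho_a, dtype=float)
    P_C = np.asarray(P_C, dtype=float)
    if np.any(rho_a < 0) or np.any(P_C < 0):
        raise ValueError("concentrations must be nonnegative")
    n = int(params.n_hill)
    out = 1.0 / (1.0 + (rho_a / params.beta_rho) ** n + (P_C / params.beta_PR) ** n)
    return float(out) if out.ndim == 0 else out


def _reaction_terms(A: np.ndarray, p: ModelParameters, mask: np.ndarray,
                    totals=None, out: np.ndarray | None = None) -> np.ndarray:
    """Reaction right-hand sides on the stacked (12, n) array.

    ``mask`` is a float (or bool) array marking the ECM-adjacent nodes where
    integrin activation operates; the decay of active integrin applies
    everywhere.  ``totals`` optionally overrides the family totals entering
    the saturating (inactive-fraction) terms with per-node arrays — used by
    the degradation/upregulation protocol where a target family's total is
    no longer the baseline constant.  Hill inputs are clipped at zero so
    round-off negatives cannot produce NaN under the integer power.
    """
    if out is None:
        out = np.empty_like(A)
    if totals is None:
        I_tot, C_tot, R_tot, rho_tot, P_tot, S_tot = (
            p.I_tot, p.C_tot, p.R_tot, p.rho_tot, p.P_tot, p.S_tot)
    else:
        I_tot, C_tot, R_tot, rho_tot, P_tot, S_tot = totals
    n = int(p.n_hill)

    rho_a = np.maximum(A[RHOA], 0.0)
    R_a = np.maximum(A[RA], 0.0)
    P_C = np.maximum(A[PC], 0.0)
    S_C = np.maximum(A[SC], 0.0)

    # integrins: activation only where connected to the ECM, decay everywhere
    net = p.I_I * (A[II] / I_tot) * mask - p.delta_I * A[IA]
    out[IA] = net
    out[II] = -net

    # Cdc42: activated by Rho plus a baseline input
    net = (p.alpha_rho * rho_a + p.I_C) * (A[CI] / C_tot) - p.delta_C * A[CA]
    out[CA] = net
    out[CI] = -net

    # Rac: activated by integrins, inhibited by Rho and Par
    inhib = 1.0 + (rho_a / p.beta_rho) ** n + (P_C / p.beta_PR) ** n
    net = (p.alpha_I * A[IA] + p.I_R) / inhib * (A[RI] / R_tot) - p.delta_R * A[RA]
    out[RA] = net
    out[RI] = -net

    # Rho: inhibited by Rac
    net = p.I_rho / (1.0 + (R_a / p.beta_R) ** n) * (A[RHOI] / rho_tot) \
        - p.delta_rho * A[RHOA]
    out[RHOA] = net
    out[RHOI] = -net

    # Par complex: binding promoted by Cdc42, inhibited by Scribble
    net = (p.alpha_C * A[CA] + p.k_on_P) / (1.0 + (S_C / p.beta_SP) ** n) \
        * (A[PUN] / P_tot) - p.k_off_P * A[PC]
    out[PC] = net
    out[PUN] = -net

    # Scribble complex: binding inhibited by Par
    net = p.k_on_S / (1.0 + (P_C / p.beta_PS) ** n) * (A[SUN] / S_tot) \
        - p.k_off_S * A[SC]
    out[SC] = net
    out[SUN] = -net
    return out


def reaction_rates(state: SpeciesState, params: ModelParameters,
                   activation_mask: np.ndarray) -> SpeciesState:
    """Per-species local reaction rates (uM/s), without diffusion.

    ``activation_mask`` is a per-node boolean marking where the integrin
    activation input applies (the ECM-adjacent region).  For every
    conjugate pair the returned rates cancel node-wise exactly.
    """
    mask = np.asarray(activation_mask)
    if mask.shape != (state.n_nodes,):
        raise ValueError(
            f"activation_mask shape {mask.shape} does not match "
            f"{state.n_nodes} grid nodes")
    A = state.as_array()
    return SpeciesState.from_array(
        _reaction_terms(A, params, mask.astype(float)))
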