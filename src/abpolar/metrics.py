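"""Polarization quantification and steady-state detection.

An output is "polarized" when the absolute apical-basal concentration
difference, expressed as a percentage of the same difference in a
reference (baseline-parameter) run, exceeds 20%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import Trajectory
from .state import OUTPUT_SPECIES, SpeciesState

__all__ = [
    "POLARIZATION_THRESHOLD_PERCENT", "OutputPolarization", "PolarizationResult",
    "apical_basal_difference", "delta_p", "classify_polarized",
    "steady_state_time", "polarization_result",
]

#: delta-P (% of reference) above which an output counts as polarized (strict)
POLARIZATION_THRESHOLD_PERCENT = 20.0


def apical_basal_difference(final_state: SpeciesState, output: str) -> float:
    """Absolute concentration difference between the apical and basal node (uM).

    The apical and basal concentrations are read at the last and first grid
    node respectively.
    """
    if output not in OUTPUT_SPECIES:
        raise ValueError(f"unknown output {output!r}; expected one of {OUTPUT_SPECIES}")
    c = getattr(final_state, output)
    return float(abs(c[-1] - c[0]))


def delta_p(test_diff: float, reference_diff: float) -> float:
    """Apical-basal difference as a percentage of the reference difference."""
    if not reference_diff > 0:
        raise ValueError("reference apical-basal difference must be positive")
    return 100.0 * test_diff / reference_diff


def classify_polarized(delta_p_percent: float) -> bool:
    """True iff delta-P strictly exceeds the 20% acceptance bound."""
    if delta_p_percent < 0:
        raise ValueError("delta-P must be nonnegative")
    return delta_p_percent > POLARIZATION_THRESHOLD_PERCENT


def steady_state_time(trajectory: Trajectory, tol: float = 1e-3) -> float | None:
    """Earliest snapshot time after which Par/Scribble profiles stop changing.

    The rate of change between consecutive snapshots is measured as the
    max-norm difference of the bound Par and Scribble fields, relative to
    the field's max-norm magnitude, per second of model time.  Returns the
    earliest snapshot time from which this rate stays below ``tol`` (per
    second) through the end of the trajectory, or None if it never does.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    times, states = trajectory.times, trajectory.states
    if len(states) < 2:
        raise ValueError("trajectory needs at least 2 snapshots")
    rates = np.empty(len(states) - 1)
    for k in range(len(states) - 1):
        dt = times[k + 1] - times[k]
        r = 0.0
        for name in ("P_C", "S_C"):
            a = getattr(states[k], name)
            b = getattr(states[k + 1], name)
            scale = max(np.abs(a).max(), 1e-30)
            r = max(r, np.abs(b - a).max() / (scale * dt))
        rates[k] = r
    below = rates < tol
    if not below[-1]:
        return None
    # last index where the rate was >= tol; steady from the snapshot after it
    above = np.nonzero(~below)[0]
    first = 0 if len(above) == 0 else above[-1] + 1
    return float(times[first])


@dataclass
class OutputPolarization:
    """Polarization summary for a single model output."""

    apical_uM: float
    basal_uM: float
    difference_uM: float
    delta_p_percent: float
    polarized: bool


@dataclass
class PolarizationResult:
    """Per-output polarization summary of a run against a reference run."""

    outputs: dict[str, OutputPolarization]
    steady_state_time_s: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {name: vars(o) for name, o in self.outputs.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "output"
        return df

    def to_json(self, path=None) -> str:
        payload = {
            "outputs": {k: vars(v) for k, v in self.outputs.items()},
            "steady_state_time_s": self.steady_state_time_s,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def polarization_result(final_state: SpeciesState, reference: SpeciesState,
                        steady_time: float | None = None) -> PolarizationResult:
    """Score all six outputs of a final state against a reference final state."""
    outputs = {}
    for name in OUTPUT_SPECIES:
        c = getattr(final_state, name)
        diff = apical_basal_difference(final_state, name)
        ref_diff = apical_basal_difference(reference, name)
        dp = delta_p(diff, ref_diff)
        outputs[name] = OutputPolarization(
            apical_uM=float(c[-1]), basal_uM=float(c[0]),
            difference_uM=diff, delta_p_percent=dp,
            polarized=classify_polarized(dp))
    return PolarizationResult(outputs=outputs, steady_state_time_s=steady_time)
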