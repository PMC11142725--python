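"""Shared fixtures: baseline parameters, grid and reference simulations."""

import numpy as np
import pytest

from abpolar import GridSpec, ModelParameters, simulate


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def baseline_traj(params, grid):
    """Baseline 100-s run with 1-s snapshots (the reference case)."""
    return simulate(params, grid, 100.0, snapshot_stride=1.0)


@pytest.fixture(scope="session")
def baseline_final(baseline_traj):
    return baseline_traj.final_state


@pytest.fixture(scope="session")
def reference_300(params, grid):
    """Unperturbed 300-s run (reference for the perturbation protocol)."""
    return simulate(params, grid, 300.0, snapshot_stride=300.0).final_state
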