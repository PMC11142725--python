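"""Discretization, initial conditions and the explicit integrator."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from abpolar import (GridSpec, ModelParameters, initial_state,
                     laplacian_noflux, simulate, step)
from abpolar.solver import IntegrationError, default_activation_mask
from abpolar.state import FAMILIES, SPECIES, SpeciesState


class TestInitialState:
    def test_cue_node_carries_full_integrin_total(self, params, grid):
        st = initial_state(params, grid)
        assert st.I_a[0] == pytest.approx(params.I_tot)

    def test_second_node_exponential_decay(self, params, grid):
        st = initial_state(params, grid)
        expected = 0.25 * math.exp(0.25 - 1.0) * params.I_tot  # ~3.543 uM
        assert st.I_a[1] == pytest.approx(expected)
        assert st.I_a[1] == pytest.approx(3.543, abs=5e-4)

    def test_interior_uniform_baseline_values(self, params, grid):
        st = initial_state(params, grid)
        np.testing.assert_array_equal(st.I_a[5:], 0.0)
        np.testing.assert_allclose(st.C_a, 0.8)
        np.testing.assert_allclose(st.rho_a, 1.0)
        np.testing.assert_allclose(st.R_a, 1.75)
        np.testing.assert_allclose(st.P_C, 0.6)
        np.testing.assert_allclose(st.S_C, 0.6)

    def test_per_node_family_sums_equal_totals(self, params, grid):
        st = initial_state(params, grid)
        st.validate(params)

    def test_apical_cue_mirrors_profile(self, params, grid):
        basal = initial_state(params, grid, "basal")
        apical = initial_state(params, grid, "apical")
        np.testing.assert_array_equal(apical.I_a, basal.I_a[::-1])

    def test_grid_too_small_rejected(self, params):
        with pytest.raises(ValueError):
            initial_state(params, GridSpec(L=1.0, n_sub=3, dt=1e-4))


class TestLaplacian:
    def test_constant_field_is_flat(self):
        np.testing.assert_array_equal(laplacian_noflux(np.full(7, 3.2), 0.5), 0.0)

    def test_linear_ramp_boundary_closure(self):
        # interior curvature zero; boundaries see the one-sided flux
        out = laplacian_noflux(np.array([0.0, 1.0, 2.0, 3.0]), 1.0)
        np.testing.assert_array_equal(out, [1.0, 0.0, 0.0, -1.0])

    def test_interior_spike_three_point_stencil(self):
        out = laplacian_noflux(np.array([0.0, 0.0, 1.0, 0.0, 0.0]), 1.0)
        np.testing.assert_array_equal(out, [0.0, 1.0, -2.0, 1.0, 0.0])

    def test_discrete_conservation(self):
        rng = np.random.default_rng(7)
        f = rng.uniform(0, 5, 31)
        assert abs(laplacian_noflux(f, 1 / 3).sum()) < 1e-10

    def test_short_field_rejected(self):
        with pytest.raises(ValueError):
            laplacian_noflux(np.array([1.0, 2.0]), 0.5)


def _flat_fixed_point(params, n):
    """Spatially uniform reaction fixed point with integrin activation
    everywhere (mask all True), found numerically for the six active pools."""
    def residual(x):
        ia, ca, ra, rhoa, pc, sc = x
        nh = params.n_hill
        r = np.empty(6)
        r[0] = params.I_I * (params.I_tot - ia) / params.I_tot - params.delta_I * ia
        r[1] = ((params.alpha_rho * rhoa + params.I_C)
                * (params.C_tot - ca) / params.C_tot - params.delta_C * ca)
        r[2] = ((params.alpha_I * ia + params.I_R)
                / (1 + (rhoa / params.beta_rho) ** nh + (pc / params.beta_PR) ** nh)
                * (params.R_tot - ra) / params.R_tot - params.delta_R * ra)
        r[3] = (params.I_rho / (1 + (ra / params.beta_R) ** nh)
                * (params.rho_tot - rhoa) / params.rho_tot
                - params.delta_rho * rhoa)
        r[4] = ((params.alpha_C * ca + params.k_on_P)
                / (1 + (sc / params.beta_SP) ** nh)
                * (params.P_tot - pc) / params.P_tot - params.k_off_P * pc)
        r[5] = (params.k_on_S / (1 + (pc / params.beta_PS) ** nh)
                * (params.S_tot - sc) / params.S_tot - params.k_off_S * sc)
        return r

    x0 = np.array([9.0, 2.0, 0.5, 1.5, 0.3, 0.8])
    x = fsolve(residual, x0, full_output=False, xtol=1e-14)
    assert np.abs(residual(x)).max() < 1e-12
    ia, ca, ra, rhoa, pc, sc = x
    actives = {"I_a": ia, "C_a": ca, "R_a": ra, "rho_a": rhoa,
               "P_C": pc, "S_C": sc}
    data = {}
    for act, inact, tot in FAMILIES:
        data[act] = np.full(n, actives[act])
        data[inact] = getattr(params, tot) - data[act]
    return SpeciesState(**data)


class TestStep:
    def test_flat_fixed_point_is_preserved(self, params, grid):
        st = _flat_fixed_point(params, grid.n_nodes)
        mask = np.ones(grid.n_nodes, dtype=bool)
        new = step(st, params, grid, mask)
        np.testing.assert_allclose(new.as_array(), st.as_array(),
                                   rtol=0, atol=1e-13)

    def test_one_step_conserves_family_sums(self, params, grid):
        st = initial_state(params, grid)
        mask = default_activation_mask(grid)
        new = step(st, params, grid, mask)
        before, after = st.family_totals(), new.family_totals()
        for k in before:
            assert after[k] == pytest.approx(before[k], rel=1e-12)

    def test_integrin_drives_rac_up_at_cue_node(self, params, grid):
        st = initial_state(params, grid)
        new = step(st, params, grid, default_activation_mask(grid))
        assert new.R_a[0] > st.R_a[0]

    def test_stability_bound_enforced(self, params):
        with pytest.raises(ValueError, match="stability"):
            simulate(params, GridSpec(dt=0.01), 1.0)

    def test_blowup_reported_with_species_and_node(self, grid):
        # pathologically fast kinetics overwhelm the explicit scheme
        bad = ModelParameters(k_off_S=1e6)
        with pytest.raises(IntegrationError):
            simulate(bad, grid, 1.0)


class TestSimulate:
    def test_t_end_zero_returns_initial_state_only(self, params, grid):
        traj = simulate(params, grid, 0.0)
        assert len(traj.states) == 1 and traj.times[0] == 0.0

    def test_snapshot_times_strictly_increasing(self, baseline_traj):
        assert np.all(np.diff(baseline_traj.times) > 0)

    def test_family_conservation_over_full_run(self, params, grid,
                                               baseline_traj):
        start = initial_state(params, grid).family_totals()
        end = baseline_traj.final_state.family_totals()
        for k, v in start.items():
            assert abs(end[k] / v - 1) < 1e-8

    def test_nonnegative_concentrations(self, baseline_traj):
        for s in SPECIES:
            assert getattr(baseline_traj.final_state, s).min() >= 0

    def test_mirror_symmetry_of_cue_side(self, params, grid):
        basal = simulate(params, grid, 5.0, cue_side="basal",
                         snapshot_stride=5.0).final_state
        apical = simulate(params, grid, 5.0, cue_side="apical",
                          snapshot_stride=5.0).final_state
        np.testing.assert_array_equal(apical.as_array(),
                                      basal.mirror().as_array())

    def test_trajectory_dataframe_is_tidy(self, params, grid):
        traj = simulate(params, grid, 1.0, snapshot_stride=0.5)
        df = traj.to_dataframe()
        assert list(df.columns) == ["time_s", "node_index", "x_um",
                                    "species", "concentration_uM"]
        assert set(df["species"]) == set(SPECIES)
        assert len(df) == len(traj.states) * len(SPECIES) * grid.n_nodes
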