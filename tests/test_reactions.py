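"""Local reaction kinetics: Hill factors and conjugate-pair rate laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abpolar import (GridSpec, ModelParameters, combined_rac_inhibition,
                     hill_inhibition, initial_state, reaction_rates)
from abpolar.state import FAMILIES, SPECIES, SpeciesState


class TestHillInhibition:
    @pytest.mark.parametrize("value, beta, n, expected", [
        (0.0, 0.7, 4, 1.0),              # no inhibitor -> no inhibition
        (0.7, 0.7, 4, 0.5),              # half-point at value == beta
        (0.2, 0.2, 1, 0.5),              # half-point independent of n
        (1.4, 0.7, 4, 1.0 / 17.0),       # 1/(1 + 2^4)
    ])
    def test_values(self, value, beta, n, expected):
        assert hill_inhibition(value, beta, n) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_inhibition(-0.1, 0.7, 4)
        with pytest.raises(ValueError):
            hill_inhibition(0.5, 0.0, 4)
        with pytest.raises(ValueError):
            hill_inhibition(0.5, 0.7, 0)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0, 50), st.floats(0, 50))
    def test_monotone_nonincreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert hill_inhibition(hi, 0.7, 4) <= hill_inhibition(lo, 0.7, 4)

    def test_bounds(self):
        vals = hill_inhibition(np.linspace(0, 100, 50), 1.5, 4)
        assert np.all(vals > 0) and np.all(vals <= 1)


class TestCombinedRacInhibition:
    def test_no_inhibitors(self, params):
        assert combined_rac_inhibition(0.0, 0.0, params) == 1.0

    def test_single_term_half_point(self, params):
        assert combined_rac_inhibition(params.beta_rho, 0.0, params) == pytest.approx(0.5)

    def test_both_terms_at_half_points(self, params):
        # both ratios equal 1 at the default inhibition constants
        assert combined_rac_inhibition(0.7, 2.0, params) == pytest.approx(1 / 3)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            combined_rac_inhibition(-1.0, 0.0, params)


def _uniform_state(params, n, **overrides):
    """Flat state with the baseline uniform actives unless overridden."""
    base = {"I_a": 0.0, "C_a": 0.8, "rho_a": 1.0, "R_a": 1.75,
            "P_C": 0.6, "S_C": 0.6}
    base.update(overrides)
    data = {}
    for act, inact, tot in FAMILIES:
        data[act] = np.full(n, base[act])
        data[inact] = getattr(params, tot) - data[act]
    return SpeciesState(**data)


class TestReactionRates:
    def test_rac_baseline_input_rate(self, params, grid):
        # no inhibitors, no integrin drive, full inactive pool -> dR_a = I_R
        st_ = _uniform_state(params, grid.n_nodes, rho_a=0.0, P_C=0.0, R_a=0.0)
        mask = np.zeros(grid.n_nodes, dtype=bool)
        rates = reaction_rates(st_, params, mask)
        np.testing.assert_allclose(rates.R_a, params.I_R)

    def test_cdc42_rho_driven_activation(self, params, grid):
        # rho_a = 1, full inactive Cdc42 pool: dC_a = alpha_rho + I_C = 3.0
        st_ = _uniform_state(params, grid.n_nodes, C_a=0.0, rho_a=1.0)
        mask = np.zeros(grid.n_nodes, dtype=bool)
        rates = reaction_rates(st_, params, mask)
        np.testing.assert_allclose(rates.C_a, params.alpha_rho * 1.0 + params.I_C)

    def test_each_activation_rate_equals_input_at_empty_active_pools(
            self, params, grid):
        st_ = _uniform_state(params, grid.n_nodes, I_a=0.0, C_a=0.0,
                             rho_a=0.0, R_a=0.0, P_C=0.0, S_C=0.0)
        mask = np.zeros(grid.n_nodes, dtype=bool)
        rates = reaction_rates(st_, params, mask)
        np.testing.assert_allclose(rates.C_a, params.I_C)
        np.testing.assert_allclose(rates.R_a, params.I_R)
        np.testing.assert_allclose(rates.rho_a, params.I_rho)
        np.testing.assert_allclose(rates.P_C, params.k_on_P)
        np.testing.assert_allclose(rates.S_C, params.k_on_S)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**32 - 1))
    def test_conjugate_pairs_cancel_nodewise(self, params, grid, seed):
        rng = np.random.default_rng(seed)
        n = grid.n_nodes
        data = {}
        for act, inact, tot in FAMILIES:
            total = getattr(params, tot)
            frac = rng.uniform(0, 1, n)
            data[act] = frac * total
            data[inact] = (1 - frac) * total
        st_ = SpeciesState(**data)
        mask = rng.uniform(0, 1, n) < 0.5
        rates = reaction_rates(st_, params, mask)
        for act, inact, _ in FAMILIES:
            np.testing.assert_array_equal(
                getattr(rates, act) + getattr(rates, inact), np.zeros(n))

    def test_rho_monotonically_steers_rac_and_cdc42(self, params, grid):
        mask = np.zeros(grid.n_nodes, dtype=bool)
        rhos = np.linspace(0, 3, 7)
        d_ra, d_ca = [], []
        for rho in rhos:
            st_ = _uniform_state(params, grid.n_nodes, rho_a=rho)
            rates = reaction_rates(st_, params, mask)
            d_ra.append(rates.R_a[0])
            d_ca.append(rates.C_a[0])
        assert np.all(np.diff(d_ra) <= 0)   # more Rho -> less Rac activation
        assert np.all(np.diff(d_ca) >= 0)   # more Rho -> more Cdc42 activation

    def test_integrin_activation_only_on_mask(self, params, grid):
        st_ = initial_state(params, grid)
        mask = np.zeros(grid.n_nodes, dtype=bool)
        mask[:5] = True
        rates = reaction_rates(st_, params, mask)
        # off-mask nodes have I_a = 0 initially, so their rate is exactly 0
        np.testing.assert_array_equal(rates.I_a[5:], 0.0)
        # the cue-adjacent node decays from I_a = I_tot with no inactive pool
        assert rates.I_a[0] == pytest.approx(-params.delta_I * params.I_tot)

    def test_mask_shape_mismatch_rejected(self, params, grid):
        st_ = initial_state(params, grid)
        with pytest.raises(ValueError):
            reaction_rates(st_, params, np.ones(grid.n_nodes + 1, dtype=bool))
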