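"""Reaction terms, parameter containers, and the homogeneous steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minwave.model_core import (
    ConcentrationField,
    DiffusionCoefficients,
    KineticParameters,
    ProteinTotals,
    SteadyStateError,
    _steady_branch,
    reaction_rates,
    uniform_steady_state,
)


def random_params(rng):
    k = 10.0 ** rng.normal(0, 1.5, size=4)
    return KineticParameters(k_D=k[0], k_dD=k[1], k_dE=k[2], k_de=0.33, k_ADP_ATP=k[3])


class TestContainers:
    def test_kinetic_parameters_reject_nonpositive(self):
        with pytest.raises(ValueError):
            KineticParameters(k_D=0.0, k_dD=1, k_dE=1, k_de=1, k_ADP_ATP=1)
        with pytest.raises(ValueError):
            KineticParameters(k_D=np.inf, k_dD=1, k_dE=1, k_de=1, k_ADP_ATP=1)

    def test_totals_scale_at_fixed_concentration(self):
        totals = ProteinTotals(minD_total=2205, minE_total=1580, reference_length=2.84)
        minD, minE = totals.scaled_to(3.0)
        assert minD == pytest.approx(2205 * 3.0 / 2.84)
        assert minE == pytest.approx(1580 * 3.0 / 2.84)

    def test_field_shape_is_validated(self):
        with pytest.raises(ValueError):
            ConcentrationField(np.arange(4.0), np.zeros((5, 3)))


class TestReactionRates:
    def test_zero_state_is_absorbing(self, params):
        u = np.zeros((5, 7))
        assert np.all(reaction_rates(u, params) == 0.0)

    def test_complex_dissociation_channel(self):
        # only the membrane MinDE complex populated: dissociation feeds
        # MinD-ADP and free MinE at k_de * c_de
        p = KineticParameters(k_D=1.66, k_dD=0.22, k_dE=0.82, k_de=0.33, k_ADP_ATP=1.09)
        u = np.zeros(5)
        u[4] = 5.0
        dc = reaction_rates(u, p)
        assert dc[0] == pytest.approx(1.65)
        assert dc[2] == pytest.approx(1.65)
        assert dc[4] == pytest.approx(-1.65)
        assert dc[1] == 0.0 and dc[3] == 0.0

    def test_mass_conservation_identity(self, rng, params):
        # reaction terms sum to zero over MinD species and over MinE
        # species at any state, to machine precision
        u = rng.uniform(0, 100, size=(5, 40))
        dc = reaction_rates(u, params)
        minD = dc[0] + dc[1] + dc[3] + dc[4]
        minE = dc[2] + dc[4]
        assert np.abs(minD).max() < 1e-10
        assert np.abs(minE).max() < 1e-10

    def test_depleted_species_never_driven_negative(self, rng, params):
        for s in range(5):
            u = rng.uniform(0, 50, size=(5, 10))
            u[s] = 0.0
            dc = reaction_rates(u, params)
            assert np.all(dc[s] >= 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        rates=st.lists(st.floats(1e-6, 1e6), min_size=5, max_size=5),
        state=st.lists(st.floats(0.0, 1e4), min_size=5, max_size=5),
    )
    def test_conservation_holds_for_arbitrary_rates_and_states(self, rates, state):
        p = KineticParameters(
            k_D=rates[0], k_dD=rates[1], k_dE=rates[2], k_de=rates[3], k_ADP_ATP=rates[4]
        )
        dc = reaction_rates(np.array(state), p)
        scale = max(np.abs(dc).max(), 1.0)
        assert abs(dc[0] + dc[1] + dc[3] + dc[4]) <= 1e-9 * scale
        assert abs(dc[2] + dc[4]) <= 1e-9 * scale

    def test_negative_density_rejected(self, params):
        u = np.zeros((5, 3))
        u[0, 1] = -1.0
        with pytest.raises(ValueError):
            reaction_rates(u, params)


class TestUniformSteadyState:
    def test_residual_and_mass_constraints(self, params, totals):
        u = uniform_steady_state(params, totals, 3.0)
        assert np.abs(reaction_rates(u, params)).max() < 1e-9
        assert u[0] + u[1] + u[3] + u[4] == pytest.approx(totals.minD_density, rel=1e-10)
        assert u[2] + u[4] == pytest.approx(totals.minE_density, rel=1e-10)
        assert np.all(u >= 0)

    def test_matches_dense_grid_search_oracle(self, params, totals):
        # independent oracle: dense scan of the MinD-mass defect over c_d,
        # then bisection polish on the bracketing pair
        rho_D, rho_E = totals.minD_density, totals.minE_density

        def defect(c_d):
            u = _steady_branch(c_d, params, rho_E)
            return u[0] + u[1] + u[3] + u[4] - rho_D

        grid = np.linspace(0, rho_D, 20001)
        vals = np.array([defect(c) for c in grid])
        (ix,) = np.nonzero(np.diff(np.sign(vals)) != 0)
        assert ix.size == 1, "physical root should be unique"
        lo, hi = grid[ix[0]], grid[ix[0] + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if defect(lo) * defect(mid) <= 0:
                hi = mid
            else:
                lo = mid
        u = uniform_steady_state(params, totals, 3.0)
        assert u[3] == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_nucleotide_exchange_balances_dissociation(self, rng, totals):
        # stationarity of the MinD-ADP pool: k_ADP_ATP * c_DD = k_de * c_de
        for _ in range(20):
            p = random_params(rng)
            u = uniform_steady_state(p, totals, 3.0)
            assert p.k_ADP_ATP * u[0] == pytest.approx(p.k_de * u[4], rel=1e-8, abs=1e-12)

    def test_vanishing_attachment_leaves_membrane_empty(self, totals):
        # with both attachment pathways (spontaneous k_D and cooperative
        # k_dD) removed, all MinD ends up cytosolic ATP-bound and all MinE
        # free; note k_D -> 0 alone is NOT enough — recruitment by membrane
        # MinD sustains a self-seeded membrane pool
        p = KineticParameters(k_D=1e-14, k_dD=1e-14, k_dE=0.82, k_de=0.33, k_ADP_ATP=1.09)
        u = uniform_steady_state(p, totals, 3.0)
        assert u[3] < 1e-6 and u[4] < 1e-6 and u[0] < 1e-6
        assert u[1] == pytest.approx(totals.minD_density, rel=1e-6)
        assert u[2] == pytest.approx(totals.minE_density, rel=1e-6)

    def test_spontaneous_attachment_limit_keeps_recruited_pool(self, totals):
        # k_D -> 0 with k_dD > 0: the cooperatively recruited membrane pool
        # survives, continuous in the limit
        p = KineticParameters(k_D=1e-14, k_dD=0.22, k_dE=0.82, k_de=0.33, k_ADP_ATP=1.09)
        u = uniform_steady_state(p, totals, 3.0)
        assert u[3] > 1.0

    def test_random_sets_all_satisfy_residual_bound(self, rng, totals):
        for _ in range(50):
            p = random_params(rng)
            u = uniform_steady_state(p, totals, 3.0)
            assert np.abs(reaction_rates(np.clip(u, 0, None), p)).max() < 1e-9 * max(
                1.0, totals.minD_density
            )
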