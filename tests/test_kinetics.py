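import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdukinetics.kinetics import (
    N_SPECIES,
    initial_state,
    mm_rate,
    net_reversible_rate,
    rhs,
    species_totals,
    transport_flux,
    wellmixed_rhs,
)
from pdukinetics.params import (
    EnzymeKinetics,
    GrowthCurve,
    Species,
    default_enzymes,
    default_parameters,
)

ZERO_VMAX = {k: 0.0 for k in (
    "vmax_CDE_mM_h", "vmax_P_mM_h", "vmax_Q_mM_h", "vmax_LW_mM_h",
    "vmax_P_rev_mM_h", "vmax_Q_rev_mM_h")}


def transport_only_params(**overrides):
    """Default geometry with enzyme activity switched off (vmax = 0)."""
    return default_parameters(enzymes=default_enzymes(ZERO_VMAX), **overrides)


def constant_growth(density=1e8):
    return GrowthCurve([0.0, 30.0], [density, density])


class TestRateLaws:
    def test_half_saturation(self):
        assert mm_rate(5.0, 10.0, 5.0) == pytest.approx(5.0)

    def test_zero_substrate(self):
        assert mm_rate(0.0, 10.0, 5.0) == 0.0

    def test_example_value(self):
        assert mm_rate(20.0, 10.0, 5.0) == pytest.approx(8.0)

    def test_negative_substrate_clamped(self):
        assert mm_rate(-1.0, 10.0, 5.0) == 0.0

    @given(
        s1=st.floats(0, 1e4),
        ds=st.floats(0, 1e4),
        vmax=st.floats(1e-3, 1e7),
        km=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, s1, ds, vmax, km):
        r1, r2 = mm_rate(s1, vmax, km), mm_rate(s1 + ds, vmax, km)
        assert r1 <= r2 <= vmax

    def test_net_reversible_example(self):
        kin = EnzymeKinetics("PduP", vmax_fwd=10.0, km_fwd=5.0, vmax_rev=4.0, km_rev=2.0)
        assert net_reversible_rate(5.0, 2.0, kin) == pytest.approx(3.0)
        assert net_reversible_rate(0.0, 0.0, kin) == 0.0

    def test_irreversible_limit_reduces_to_forward(self):
        kin = EnzymeKinetics("PduP", vmax_fwd=10.0, km_fwd=5.0, vmax_rev=0.0)
        assert net_reversible_rate(7.0, 123.0, kin) == mm_rate(7.0, 10.0, 5.0)

    @given(
        a=st.floats(0, 100), b=st.floats(0, 100),
        perm=st.floats(0, 1e6), area=st.floats(0, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_transport_antisymmetry(self, a, b, perm, area):
        assert transport_flux(perm, area, a, b) == -transport_flux(perm, area, b, a)

    def test_transport_examples(self):
        assert transport_flux(1.0, 2.0, 3.0, 1.0) == pytest.approx(4.0)
        assert transport_flux(0.0, 2.0, 3.0, 1.0) == 0.0
        assert transport_flux(5.0, 2.0, 2.5, 2.5) == 0.0


class TestRhs:
    def test_zero_state_is_fixed_point(self):
        p = default_parameters()
        g = constant_growth()
        assert np.all(rhs(0.0, np.zeros(3 * N_SPECIES), p, g) == 0.0)
        assert np.all(wellmixed_rhs(0.0, np.zeros(2 * N_SPECIES), p, g) == 0.0)

    def test_pure_transport_signs_and_mole_balance(self):
        """With enzymes off, 55 mM external PDO only drains into the cell."""
        p = transport_only_params()
        g = constant_growth()
        dy = rhs(0.0, initial_state(p), p, g)
        d_lum, d_cyt, d_ext = dy[:5], dy[5:10], dy[10:]
        assert d_ext[Species.PDO] < 0
        assert d_cyt[Species.PDO] > 0
        assert d_lum[Species.PDO] == 0.0  # lumen only exchanges with cytosol
        others = [s for s in Species if s != Species.PDO]
        for block in (d_lum, d_cyt, d_ext):
            assert all(block[s] == 0.0 for s in others)
        # instantaneous mole balance between medium and cytosol
        rho = g.density_per_um3(0.0)
        assert d_ext[Species.PDO] + rho * p.cytosol_volume * d_cyt[Species.PDO] == (
            pytest.approx(0.0, abs=1e-12)
        )

    @given(state=st.lists(st.floats(0, 100), min_size=15, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_transport_conserves_each_species(self, state):
        """d/dt of the weighted species totals vanishes when vmax = 0."""
        p = transport_only_params()
        g = constant_growth()
        rho = g.density_per_um3(0.0)
        dy = np.asarray(rhs(0.0, np.asarray(state), p, g))
        d_tot = species_totals(dy, p, rho)
        scale = max(1.0, float(np.max(np.abs(state))))
        assert np.all(np.abs(d_tot) < 1e-9 * scale)

    @given(state=st.lists(st.floats(0, 100), min_size=15, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_reactions_conserve_carbon_skeleton(self, state):
        """Every reaction is 1:1, so the summed totals are conserved even
        with full enzyme activity (at constant cell density)."""
        p = default_parameters()
        g = constant_growth()
        rho = g.density_per_um3(0.0)
        dy = np.asarray(rhs(0.0, np.asarray(state), p, g))
        d_carbon = species_totals(dy, p, rho).sum()
        # compare against the magnitude of the gross fluxes involved
        scale = max(1.0, float(np.max(np.abs(species_totals(dy, p, rho)))))
        assert abs(d_carbon) < 1e-7 * scale

    def test_wellmixed_transport_conserves(self):
        p = transport_only_params()
        g = constant_growth()
        state = np.linspace(1.0, 10.0, 2 * N_SPECIES)
        dy = wellmixed_rhs(0.0, state, p, g)
        d_tot = species_totals(dy, p, g.density_per_um3(0.0))
        assert np.all(np.abs(d_tot) < 1e-10)
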