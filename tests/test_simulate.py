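import numpy as np
import pytest

from pdukinetics.geometry import ParameterError
from pdukinetics.params import GrowthCurve, Species, default_parameters
from pdukinetics.simulate import (
    depletion_time,
    doubling_time,
    onset_time,
    peak,
    run_simulation,
)
from tests.test_kinetics import constant_growth, transport_only_params


class TestSummaries:
    def test_onset_linear_ramp(self):
        t = np.arange(0.0, 6.0)
        assert onset_time(t, t.copy(), 2.0) == pytest.approx(2.0)

    def test_onset_never_crossed(self):
        t = np.arange(0.0, 6.0)
        assert onset_time(t, np.zeros_like(t), 1.0) is None

    def test_onset_empty_series(self):
        with pytest.raises(ParameterError):
            onset_time([], [], 1.0)

    def test_depletion_linear(self):
        t = np.linspace(0, 11, 111)
        assert depletion_time(t, 55.0 - 5.0 * t, 0.55) == pytest.approx(10.89)

    def test_depletion_never(self):
        t = np.arange(0.0, 5.0)
        assert depletion_time(t, np.full_like(t, 10.0), 1.0) is None

    def test_peak_parabola_refined_exactly(self):
        t = np.arange(0.0, 11.0)
        t_pk, c_pk = peak(t, -((t - 5.3) ** 2) + 9.0)
        assert t_pk == pytest.approx(5.3)
        assert c_pk == pytest.approx(9.0)

    def test_peak_monotone_series_at_first_point(self):
        t = np.arange(0.0, 5.0)
        assert peak(t, 10.0 - t) == (0.0, 10.0)

    def test_doubling_time_exact_exponential(self):
        t = np.linspace(0, 10, 21)
        g = GrowthCurve(t, 1e7 * 2 ** (t / 2.0))
        assert doubling_time(g, (0, 10)) == pytest.approx(2.0)

    def test_doubling_time_flat_is_infinite(self):
        g = GrowthCurve([0, 1, 2], [5.0, 5.0, 5.0])
        with pytest.warns(UserWarning):
            assert doubling_time(g, (0, 2)) == np.inf


class TestIntegration:
    def test_isolated_system_stays_at_initial_condition(self):
        p = transport_only_params(membrane_permeability=0.0)
        res = run_simulation(p, constant_growth(), t_span=(0, 5), output_grid=0.5)
        assert np.allclose(res.trajectory, res.trajectory[0][None, :], atol=1e-12)
        ext_pdo = res.series("external", Species.PDO)
        assert np.allclose(ext_pdo, 55.0)

    def test_transport_only_reaches_shared_equilibrium(self):
        """Two-pool analytics: all regions equilibrate to total/(weighted volume)."""
        p = transport_only_params()
        g = constant_growth(density=1e9)  # dense culture: visible depletion
        res = run_simulation(p, g, t_span=(0, 40), output_grid=0.5)
        rho = g.density_per_um3(0.0)
        v_cell = p.compartments.total_volume + p.cytosol_volume
        c_eq = 55.0 / (1.0 + rho * v_cell)
        for region in ("lumen", "cytosol", "external"):
            assert res.series(region, Species.PDO)[-1] == pytest.approx(c_eq, rel=1e-6)
        assert res.conservation_residual() < 1e-8

    def test_deterministic_replay(self, base_params, growth, base_result):
        res2 = run_simulation(base_params, growth)
        assert np.array_equal(res2.trajectory, base_result.trajectory)

    def test_grid_refinement_stability(self, base_params, growth, base_result):
        """Halving the output grid moves onset/depletion/peak times < 0.1 h."""
        fine = run_simulation(base_params, growth, output_grid=0.05)
        for res_a, res_b in [(base_result, fine)]:
            for extractor in (
                lambda r: onset_time(r.times, r.series("external", Species.PROP), 1.0),
                lambda r: depletion_time(r.times, r.series("external", Species.PDO), 0.55),
                lambda r: peak(r.times, r.series("external", Species.PALD))[0],
            ):
                assert abs(extractor(res_a) - extractor(res_b)) < 0.1

    def test_base_case_timescales(self, base_params, base_result):
        """The calibrated base case reproduces the observed pathway timescales."""
        res = base_result
        t_dep = depletion_time(
            res.times, res.series("external", Species.PDO),
            0.01 * base_params.initial_external_pdo,
        )
        assert 10.0 <= t_dep <= 20.0
        t_on = onset_time(res.times, res.series("external", Species.PROP), 1.0)
        assert t_on == pytest.approx(10.0, abs=1.0)
        assert peak(res.times, res.series("cytosol", Species.PALD))[1] <= 16.0

    def test_solver_diagnostics_present(self, base_result):
        d = base_result.diagnostics
        assert d["success"]
        assert d["conservation_residual"] < 0.005

    def test_tidy_frame_shape(self, base_result):
        df = base_result.to_frame()
        assert set(df.columns) == {"time_h", "region", "species", "concentration_mM"}
        assert len(df) == len(base_result.times) * 15
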