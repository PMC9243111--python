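import numpy as np
import pytest

from pdukinetics.geometry import ParameterError
from pdukinetics.params import Species, default_parameters
from pdukinetics.simulate import doubling_time, run_simulation
from pdukinetics.synth import (
    GrowthModel,
    NoiseModel,
    generate_dataset,
    generate_growth_curve,
)


class TestGrowthGenerator:
    def test_initial_density(self):
        m = GrowthModel()
        curve = generate_growth_curve(m)
        assert curve.density_per_ml(0.0) == pytest.approx(m.n0)

    def test_lag_phase_is_flat(self):
        curve = generate_growth_curve(GrowthModel())
        assert curve.density_per_ml(2.9) == pytest.approx(curve.density_per_ml(0.0))

    def test_windowed_doubling_times_recover_generator_values(self):
        """Log-linear fits in the measurement windows return the printed
        wild-type doubling times (3.17 h early, 9.2 h late)."""
        curve = generate_growth_curve(GrowthModel())
        assert doubling_time(curve, (3.0, 9.0)) == pytest.approx(3.17, rel=0.02)
        assert doubling_time(curve, (12.0, 18.0)) == pytest.approx(9.2, rel=0.02)

    def test_continuity_at_phase_switch(self):
        m = GrowthModel()
        curve = generate_growth_curve(m)
        eps = 1e-6
        assert curve.density_per_ml(m.t_switch - eps) == pytest.approx(
            curve.density_per_ml(m.t_switch + eps), rel=1e-4
        )

    def test_growth_must_slow_down(self):
        with pytest.raises(ParameterError):
            GrowthModel(td_early=9.2, td_late=3.17)


@pytest.fixture(scope="module")
def truth():
    return default_parameters()


class TestDatasetGenerator:
    def test_noiseless_dataset_equals_model_output(self, truth):
        ds = generate_dataset(truth, GrowthModel(), NoiseModel(cv=0.0, detection_floor=0.0))
        res = run_simulation(truth, ds.growth)
        for df in ds.metabolites:
            for sp in ("PDO", "PALD", "POH", "PROP"):
                sub = df[df["species"] == sp]
                model = np.interp(
                    sub["time_h"], res.times, res.series("external", Species[sp])
                )
                assert np.allclose(sub["concentration_mM"], model, rtol=1e-9)

    def test_same_seed_reproduces_dataset(self, truth):
        a = generate_dataset(truth, noise=NoiseModel(seed=17))
        b = generate_dataset(truth, noise=NoiseModel(seed=17))
        for da, db in zip(a.metabolites, b.metabolites):
            assert np.array_equal(da["concentration_mM"], db["concentration_mM"])

    def test_different_seeds_differ(self, truth):
        a = generate_dataset(truth, noise=NoiseModel(seed=1))
        b = generate_dataset(truth, noise=NoiseModel(seed=2))
        assert not np.array_equal(
            a.metabolites[0]["concentration_mM"], b.metabolites[0]["concentration_mM"]
        )

    def test_censoring_and_nonnegativity(self, truth):
        ds = generate_dataset(truth, noise=NoiseModel(cv=0.3, seed=3))
        tidy = ds.tidy()
        c = tidy["concentration_mM"].to_numpy()
        assert np.all(c >= 0)
        assert np.all((c == 0) | (c >= ds.noise.detection_floor))

    def test_replicate_cv_matches_noise_model(self, truth):
        """Across replicates and seeds the empirical CV ~ the nominal 5%."""
        cvs = []
        for seed in range(10):
            ds = generate_dataset(truth, noise=NoiseModel(cv=0.05, seed=seed))
            wide = ds.tidy().pivot_table(
                index=["species", "time_h"], columns="replicate",
                values="concentration_mM",
            )
            vals = wide.to_numpy()
            keep = np.all(vals > 0, axis=1) & (vals.mean(axis=1) > 5.0)
            cvs.append(np.mean(vals[keep].std(axis=1, ddof=1) / vals[keep].mean(axis=1)))
        assert np.mean(cvs) == pytest.approx(0.05, rel=0.3)
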