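"""Synthetic growth curves and metabolite measurements.

Emulates the statistical structure of the study's measurements so that
calibration and parameter recovery can be exercised without any external
data: a biphasic batch growth curve (fast early phase, slow late phase)
and replicate external-metabolite time series with multiplicative
(lognormal) measurement noise and a detection floor, as for HPLC
quantification against standards.

The generator's defaults are the wild-type study conditions: doubling
time 3.17 h in the early phase and 9.2 h in the late phase, sampling
every 3 h over 30 h, 3 replicates, 55 mM initial 1,2-propanediol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ParameterError
from .params import GrowthCurve, PduModelParameters, Species
from .simulate import run_simulation

__all__ = [
    "GrowthModel",
    "NoiseModel",
    "SyntheticDataset",
    "generate_growth_curve",
    "generate_dataset",
]


@dataclass(frozen=True)
class GrowthModel:
    """Piecewise-exponential batch growth.

    Density is constant during the lag, doubles every ``td_early`` hours
    until ``t_switch``, then every ``td_late`` hours; continuous at the
    joins.  Piecewise-exponential (rather than logistic) makes the
    windowed doubling times exact generator parameters.
    """

    n0: float = 1.0e7  # cells/mL at t=0
    lag: float = 3.0  # h
    td_early: float = 3.17  # h (wild type, measured 3-9 h)
    t_switch: float = 12.0  # h, start of the observed slow phase
    td_late: float = 9.2  # h (wild type, measured 12-18 h)

    def __post_init__(self) -> None:
        if min(self.n0, self.lag, self.td_early, self.t_switch, self.td_late) <= 0:
            raise ParameterError("all growth-model fields must be positive")
        if self.td_early > self.td_late:
            raise ParameterError("growth must slow down (td_early <= td_late)")
        if self.t_switch < self.lag:
            raise ParameterError("t_switch must not precede the lag phase")

    def density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        early = np.clip(t - self.lag, 0.0, self.t_switch - self.lag)
        late = np.clip(t - self.t_switch, 0.0, None)
        return self.n0 * 2.0 ** (early / self.td_early + late / self.td_late)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model for the metabolite tables.

    Multiplicative lognormal noise with relative SD ``cv``; concentrations
    below ``detection_floor`` are reported as 0.  Replicate-specific RNG
    streams are derived deterministically from ``seed``.
    """

    cv: float = 0.05
    detection_floor: float = 0.5  # mM
    sampling_times: tuple = tuple(float(t) for t in range(0, 31, 3))
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ParameterError("cv must be nonnegative")
        if self.replicates < 1:
            raise ParameterError("need at least one replicate")


@dataclass
class SyntheticDataset:
    """Generated measurements plus the ground truth that produced them."""

    growth: GrowthCurve
    metabolites: list  # one tidy DataFrame per replicate
    truth: PduModelParameters
    noise: NoiseModel

    def tidy(self) -> pd.DataFrame:
        frames = []
        for i, df in enumerate(self.metabolites, start=1):
            d = df.copy()
            d.insert(0, "replicate", i)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def generate_growth_curve(model: GrowthModel, sampling_times=None) -> GrowthCurve:
    """Sample the growth model on a grid (default: every 0.5 h over 30 h).

    Phase breakpoints are included so the log-linear interpolation of
    :class:`GrowthCurve` reproduces the model exactly at all times.
    """
    if sampling_times is None:
        sampling_times = np.arange(0.0, 30.0 + 0.25, 0.5)
    t = np.union1d(
        np.asarray(sampling_times, dtype=float), [model.lag, model.t_switch]
    )
    return GrowthCurve(t, model.density(t))


EXTERNAL_SPECIES = (Species.PDO, Species.PALD, Species.POH, Species.PROP)


def generate_dataset(
    truth: PduModelParameters,
    growth_model: GrowthModel | None = None,
    noise: NoiseModel | None = None,
    t_span=(0.0, 30.0),
    **solver_kw,
) -> SyntheticDataset:
    """Forward-simulate at ``truth`` and emit noisy replicate tables.

    The measured species are the four externally quantified metabolites
    (propionyl-CoA is intracellular and not observed).
    """
    growth_model = growth_model or GrowthModel()
    noise = noise or NoiseModel()
    growth = generate_growth_curve(growth_model)
    times = np.asarray(noise.sampling_times, dtype=float)

    res = run_simulation(truth, growth, t_span=t_span, output_grid=0.1, **solver_kw)
    clean = {
        sp.name: np.interp(times, res.times, res.series("external", sp))
        for sp in EXTERNAL_SPECIES
    }

    master = np.random.SeedSequence(noise.seed)
    tables = []
    for child in master.spawn(noise.replicates):
        rng = np.random.default_rng(child)
        rows = []
        for sp in EXTERNAL_SPECIES:
            c = clean[sp.name].copy()
            if noise.cv > 0:
                c = c * np.exp(rng.normal(0.0, noise.cv, size=c.size))
            c[c < noise.detection_floor] = 0.0
            rows.append(
                pd.DataFrame(
                    {"time_h": times, "species": sp.name, "concentration_mM": c}
                )
            )
        tables.append(pd.concat(rows, ignore_index=True))
    return SyntheticDataset(growth=growth, metabolites=tables, truth=truth, noise=noise)
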