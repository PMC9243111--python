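"""Model parameters: species, enzyme kinetics, growth coupling, defaults.

Units used throughout the model: concentrations mM, time h, lengths um,
areas um^2, volumes um^3, permeabilities um/h, maximal rates mM/h
(referred to the volume of the region where the enzyme acts).  These keep
state magnitudes of order 1-100 over the 30 h experimental horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .geometry import (
    CellGeometry,
    CompartmentEnsemble,
    ParameterError,
    make_capsule_cell,
    make_sphere,
)

__all__ = [
    "Species",
    "SPECIES_NAMES",
    "EnzymeKinetics",
    "GrowthCurve",
    "PduModelParameters",
    "default_enzymes",
    "default_parameters",
    "parameter_manifest",
    "CELLS_PER_ML_TO_PER_UM3",
]

# 1 mL = 1e12 um^3
CELLS_PER_ML_TO_PER_UM3 = 1.0e-12


class Species(IntEnum):
    """The five modelled metabolites (concentrations in mM)."""

    PDO = 0  # 1,2-propanediol
    PALD = 1  # propionaldehyde
    PCOA = 2  # propionyl-CoA
    POH = 3  # 1-propanol
    PROP = 4  # propionate


SPECIES_NAMES = tuple(s.name for s in Species)


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten kinetics for one pathway step.

    ``vmax_fwd``/``vmax_rev`` are maximal rates (mM/h) referred to the
    volume of the region where the enzyme acts; ``vmax_rev = 0`` marks an
    irreversible step.  The reversible steps use independent forward and
    reverse Michaelis-Menten terms.
    """

    name: str  # PduCDE | PduP | PduQ | PduLW
    vmax_fwd: float
    km_fwd: float
    vmax_rev: float = 0.0
    km_rev: float = 1.0

    def __post_init__(self) -> None:
        # vmax_fwd = 0 is allowed: it is the switched-off limit used by
        # transport-only conservation checks
        if self.vmax_fwd < 0 or self.km_fwd <= 0:
            raise ParameterError(
                f"{self.name}: vmax_fwd must be nonnegative and km_fwd positive"
            )
        if self.vmax_rev < 0:
            raise ParameterError(f"{self.name}: vmax_rev must be nonnegative")
        if self.vmax_rev > 0 and self.km_rev <= 0:
            raise ParameterError(f"{self.name}: km_rev must be positive when reversible")
        if self.name in ("PduCDE", "PduLW") and self.vmax_rev != 0:
            raise ParameterError(f"{self.name} is irreversible in this model")


class GrowthCurve:
    """Time-indexed cell density with exponential-in-between interpolation.

    Interpolation is piecewise-linear in log(density) (growth is
    multiplicative), with constant extrapolation beyond the endpoints.
    Densities are cells/mL.
    """

    def __init__(self, times_h, cell_density_per_ml) -> None:
        t = np.asarray(times_h, dtype=float)
        d = np.asarray(cell_density_per_ml, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ParameterError("growth curve needs at least two time points")
        if not np.all(np.diff(t) > 0):
            raise ParameterError("growth-curve times must be strictly increasing")
        if d.shape != t.shape or np.any(d <= 0):
            raise ParameterError("growth-curve densities must be positive")
        self.times = t
        self.cell_density = d
        self._log_d = np.log(d)

    def density_per_ml(self, t) -> np.ndarray | float:
        return np.exp(np.interp(t, self.times, self._log_d))

    def density_per_um3(self, t) -> np.ndarray | float:
        return self.density_per_ml(t) * CELLS_PER_ML_TO_PER_UM3

    def __eq__(self, other) -> bool:  # value semantics, used in round-trip tests
        return (
            isinstance(other, GrowthCurve)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.cell_density, other.cell_density)
        )


def _constant_growth(density_per_ml: float = 1.0e7) -> GrowthCurve:
    return GrowthCurve([0.0, 1.0], [density_per_ml, density_per_ml])


@dataclass(frozen=True)
class PduModelParameters:
    """Complete parameter set of the three-region pathway model.

    ``shell_permeability`` (k_c) applies to every species and to the
    lateral compartment surface; end caps of cylinders additionally see
    ``end_permeability_multiplier`` (0 = closed ends, 1 = ends as
    permeable as the walls).  ``membrane_permeability`` (k_m) governs
    cell-membrane exchange with the medium.

    ``enzyme_scaling_mode``:
      * "fixed_total_enzyme" - lumen vmax values are referred to the
        reference compartment volume ``reference_lumen_volume`` (the
        base-case MCP total); changing the compartment ensemble rescales
        concentrations so total enzyme per cell is conserved.
      * "fixed_concentration" - lumen vmax values apply as-is regardless
        of the compartment volume.
    """

    compartments: CompartmentEnsemble
    cell: CellGeometry
    enzymes: dict[str, EnzymeKinetics]
    shell_permeability: float  # k_c, um/h
    membrane_permeability: float  # k_m, um/h
    end_permeability_multiplier: float = 0.0
    initial_external_pdo: float = 55.0  # mM
    enzyme_scaling_mode: str = "fixed_total_enzyme"
    reference_lumen_volume: float | None = None  # um^3; None -> own total volume

    def __post_init__(self) -> None:
        if self.shell_permeability < 0 or self.membrane_permeability < 0:
            raise ParameterError("permeabilities must be nonnegative")
        if self.end_permeability_multiplier < 0:
            raise ParameterError("end permeability multiplier must be nonnegative")
        if self.initial_external_pdo < 0:
            raise ParameterError("initial external 1,2-propanediol must be nonnegative")
        if self.enzyme_scaling_mode not in ("fixed_total_enzyme", "fixed_concentration"):
            raise ParameterError(
                f"unknown enzyme scaling mode {self.enzyme_scaling_mode!r}"
            )
        for req in ("PduCDE", "PduP", "PduQ", "PduLW"):
            if req not in self.enzymes:
                raise ParameterError(f"missing kinetics for {req}")
        if self.cytosol_volume <= 0:
            raise ParameterError(
                "total compartment volume exceeds the cell volume "
                "(cytosol volume must be positive)"
            )

    # ---- derived geometry -------------------------------------------------
    @property
    def cytosol_volume(self) -> float:
        return self.cell.cell_volume - self.compartments.total_volume

    @property
    def effective_shell_conductance(self) -> float:
        """k_c * effective area summed over all compartments (um^3/h)."""
        ens = self.compartments
        area_eff = (
            ens.total_area_lateral
            + self.end_permeability_multiplier * ens.total_area_ends
        )
        return self.shell_permeability * area_eff

    def lumen_vmax_scale(self) -> float:
        """Factor applied to lumen vmax values under the scaling mode."""
        if self.enzyme_scaling_mode == "fixed_concentration":
            return 1.0
        ref = self.reference_lumen_volume
        if ref is None:
            return 1.0
        v = self.compartments.total_volume
        if v <= 0:
            raise ParameterError("compartment volume must be positive")
        return ref / v

    def with_updates(self, **changes) -> "PduModelParameters":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Default parameter set (the calibrated base case).
#
# Geometry values are as printed in the study: 15 spherical MCPs of 140 nm
# diameter per 2.5 um capsule-shaped cell, 55 mM initial external
# 1,2-propanediol.  Kinetic constants and permeabilities are design
# defaults of this package, chosen so the stated calibration criteria
# (propionaldehyde timescale matched, peak below the 16 mM toxicity level)
# are met; see docs/methods.md.
# ---------------------------------------------------------------------------

_DEFAULTS = [
    # key, value, units, provenance ("printed" = printed in the study,
    # "default" = design default of this package)
    ("mcp_diameter_nm", 140.0, "nm", "printed"),
    ("mcps_per_cell", 15.0, "1/cell", "printed"),
    ("mt_diameter_nm", 50.0, "nm", "printed"),
    ("cell_length_um", 2.5, "um", "printed"),
    ("cell_radius_um", 0.5, "um", "default"),
    ("initial_external_pdo_mM", 55.0, "mM", "printed"),
    ("shell_permeability_um_h", 1.0e5, "um/h", "default"),
    ("membrane_permeability_um_h", 1.0e5, "um/h", "default"),
    ("end_permeability_multiplier", 0.0, "-", "default"),
    ("vmax_CDE_mM_h", 2.5e6, "mM/h", "default"),
    ("km_CDE_mM", 0.5, "mM", "default"),
    ("vmax_P_mM_h", 1.65e7, "mM/h", "default"),
    ("km_P_mM", 200.0, "mM", "default"),
    ("vmax_P_rev_mM_h", 1.65e6, "mM/h", "default"),
    ("km_P_rev_mM", 200.0, "mM", "default"),
    ("vmax_Q_mM_h", 1.5e7, "mM/h", "default"),
    ("km_Q_mM", 200.0, "mM", "default"),
    ("vmax_Q_rev_mM_h", 1.5e6, "mM/h", "default"),
    ("km_Q_rev_mM", 300.0, "mM", "default"),
    ("vmax_LW_mM_h", 5.0e4, "mM/h", "default"),
    ("km_LW_mM", 0.5, "mM", "default"),
]

DEFAULT_VALUES = {k: v for k, v, _, _ in _DEFAULTS}


def parameter_manifest() -> list[dict]:
    """Machine-readable list of every default: key, value, units, provenance."""
    return [
        {"key": k, "value": v, "units": u, "provenance": p}
        for k, v, u, p in _DEFAULTS
    ]


def default_enzymes(values: dict | None = None) -> dict[str, EnzymeKinetics]:
    v = dict(DEFAULT_VALUES)
    if values:
        v.update(values)
    return {
        "PduCDE": EnzymeKinetics("PduCDE", v["vmax_CDE_mM_h"], v["km_CDE_mM"]),
        "PduP": EnzymeKinetics(
            "PduP", v["vmax_P_mM_h"], v["km_P_mM"], v["vmax_P_rev_mM_h"], v["km_P_rev_mM"]
        ),
        "PduQ": EnzymeKinetics(
            "PduQ", v["vmax_Q_mM_h"], v["km_Q_mM"], v["vmax_Q_rev_mM_h"], v["km_Q_rev_mM"]
        ),
        "PduLW": EnzymeKinetics("PduLW", v["vmax_LW_mM_h"], v["km_LW_mM"]),
    }


def default_parameters(**overrides) -> PduModelParameters:
    """The base spherical-MCP parameter set (15 x 140 nm MCPs per cell)."""
    v = DEFAULT_VALUES
    sphere = make_sphere(v["mcp_diameter_nm"])
    ensemble = CompartmentEnsemble(geometry=sphere, count=v["mcps_per_cell"])
    cell = make_capsule_cell(v["cell_radius_um"], v["cell_length_um"])
    base = PduModelParameters(
        compartments=ensemble,
        cell=cell,
        enzymes=default_enzymes(),
        shell_permeability=v["shell_permeability_um_h"],
        membrane_permeability=v["membrane_permeability_um_h"],
        end_permeability_multiplier=v["end_permeability_multiplier"],
        initial_external_pdo=v["initial_external_pdo_mM"],
        enzyme_scaling_mode="fixed_total_enzyme",
        reference_lumen_volume=ensemble.total_volume,
    )
    return base.with_updates(**overrides) if overrides else base
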