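"""Local sensitivity analysis of model outputs.

Normalized sensitivities S = (p/Q)(dQ/dp) — the log-log slope of a
quantity of interest Q with respect to a parameter p — are estimated by
central finite differences with a relative step (default 1%).

The morphological parameters are treated as independent coordinates of
the compiled model rather than raw shape dimensions, because raw
dimensions are confounded: a compartment radius change moves the total
shell area twice as fast as an area change itself (A ~ r^2) and the
encapsulated volume three times as fast.  The sweep therefore perturbs:

* ``total_surface_area`` — compartment count scaled at fixed
  per-compartment geometry under fixed total enzyme (the pure
  transport-area lever; encapsulated volume rides along but is inert
  when enzyme totals are conserved);
* ``compartment_radius`` — radius scaled with the count rescaled to hold
  total shell area fixed (isolates compartment size/volume from area);
* ``compartment_count`` — count scaled at fixed enzyme concentration
  (each added compartment carries its own enzyme complement);
* ``cell_radius``, ``cell_length`` — capsule dimensions (membrane area
  and cytosolic volume).

Kinetic and transport scalars (permeabilities, vmax, Km) are perturbed
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import CompartmentEnsemble, CompartmentGeometry, ParameterError
from .params import GrowthCurve, PduModelParameters, Species
from .simulate import peak, run_simulation

__all__ = [
    "SensitivityReport",
    "peak_external_pald",
    "local_sensitivity",
    "sensitivity_sweep",
    "MORPHOLOGICAL_PARAMETERS",
    "KINETIC_PARAMETERS",
]


@dataclass(frozen=True)
class SensitivityReport:
    parameter: str
    qoi: str
    sensitivity: float  # dimensionless, (p/Q) dQ/dp
    rel_step: float
    scheme: str = "central"


def peak_external_pald(result) -> float:
    """Default quantity of interest: maximum external propionaldehyde (mM)."""
    return peak(result.times, result.series("external", Species.PALD))[1]


peak_external_pald.name = "peak_external_pald"


# ---------------------------------------------------------------------------
# parameter perturbations: name -> params' = f(params, factor)
# ---------------------------------------------------------------------------

def _scale_count(params: PduModelParameters, f: float) -> PduModelParameters:
    ens = params.compartments
    return params.with_updates(
        compartments=CompartmentEnsemble(geometry=ens.geometry, count=ens.count * f)
    )


def _scale_total_area(params: PduModelParameters, f: float) -> PduModelParameters:
    # count scaling at fixed per-compartment geometry; enzyme totals are
    # conserved by the fixed_total_enzyme reference volume
    if params.enzyme_scaling_mode != "fixed_total_enzyme":
        raise ParameterError(
            "total_surface_area perturbation requires fixed_total_enzyme scaling"
        )
    return _scale_count(params, f)


def _scale_count_fixed_conc(params: PduModelParameters, f: float) -> PduModelParameters:
    # adding compartments adds their enzymes: keep lumen concentrations by
    # moving the reference volume with the ensemble
    p = _scale_count(params, f)
    if p.enzyme_scaling_mode == "fixed_total_enzyme":
        ref = params.reference_lumen_volume
        if ref is None:
            ref = params.compartments.total_volume
        p = p.with_updates(reference_lumen_volume=ref * f)
    return p


def _scale_radius_fixed_area(params: PduModelParameters, f: float) -> PduModelParameters:
    # r -> f*r with count rescaled so the total shell area is unchanged
    ens = params.compartments
    g = ens.geometry
    g2 = CompartmentGeometry(
        shape=g.shape,
        radius=g.radius * f,
        length=g.length,
        include_end_area=g.include_end_area,
    )
    count2 = ens.count * g.area_per_compartment / g2.area_per_compartment
    return params.with_updates(
        compartments=CompartmentEnsemble(geometry=g2, count=count2)
    )


def _scale_cell(params: PduModelParameters, f: float, which: str) -> PduModelParameters:
    cell = params.cell
    r = cell.capsule_radius * (f if which == "radius" else 1.0)
    L = cell.cell_length * (f if which == "length" else 1.0)
    return params.with_updates(cell=type(cell)(capsule_radius=r, cell_length=L))


def _scale_enzyme(name: str, field: str):
    def apply(params: PduModelParameters, f: float) -> PduModelParameters:
        enz = dict(params.enzymes)
        enz[name] = replace(enz[name], **{field: getattr(enz[name], field) * f})
        return params.with_updates(enzymes=enz)

    return apply


MORPHOLOGICAL_PARAMETERS = {
    "total_surface_area": _scale_total_area,
    "compartment_radius": _scale_radius_fixed_area,
    "compartment_count": _scale_count_fixed_conc,
    "cell_radius": lambda p, f: _scale_cell(p, f, "radius"),
    "cell_length": lambda p, f: _scale_cell(p, f, "length"),
}

KINETIC_PARAMETERS = {
    "shell_permeability": lambda p, f: p.with_updates(
        shell_permeability=p.shell_permeability * f
    ),
    "membrane_permeability": lambda p, f: p.with_updates(
        membrane_permeability=p.membrane_permeability * f
    ),
    "vmax_CDE": _scale_enzyme("PduCDE", "vmax_fwd"),
    "km_CDE": _scale_enzyme("PduCDE", "km_fwd"),
    "vmax_P": _scale_enzyme("PduP", "vmax_fwd"),
    "km_P": _scale_enzyme("PduP", "km_fwd"),
    "vmax_P_rev": _scale_enzyme("PduP", "vmax_rev"),
    "vmax_Q": _scale_enzyme("PduQ", "vmax_fwd"),
    "km_Q": _scale_enzyme("PduQ", "km_fwd"),
    "vmax_Q_rev": _scale_enzyme("PduQ", "vmax_rev"),
    "vmax_LW": _scale_enzyme("PduLW", "vmax_fwd"),
    "km_LW": _scale_enzyme("PduLW", "km_fwd"),
    "initial_external_pdo": lambda p, f: p.with_updates(
        initial_external_pdo=p.initial_external_pdo * f
    ),
}

ALL_PARAMETERS = {**MORPHOLOGICAL_PARAMETERS, **KINETIC_PARAMETERS}


def local_sensitivity(
    params: PduModelParameters,
    growth: GrowthCurve,
    parameter: str,
    qoi=peak_external_pald,
    rel_step: float = 0.01,
    perturb=None,
    **solver_kw,
) -> SensitivityReport:
    """Central-difference normalized sensitivity of ``qoi`` to ``parameter``.

    S = [Q(p(1+e)) - Q(p(1-e))] / (2 e Q(p)); ``perturb`` may supply a
    custom perturbation function (params, factor) -> params.
    """
    if perturb is None:
        try:
            perturb = ALL_PARAMETERS[parameter]
        except KeyError:
            raise ParameterError(f"unknown parameter {parameter!r}") from None
    if not 0 < rel_step < 1:
        raise ParameterError("rel_step must be in (0, 1)")

    def q_at(factor: float) -> float:
        p = perturb(params, factor)
        return float(qoi(run_simulation(p, growth, **solver_kw)))

    q0 = q_at(1.0)
    if q0 == 0:
        raise ParameterError(
            f"quantity of interest is zero at the base point; normalized "
            f"sensitivity to {parameter!r} is undefined"
        )
    s = (q_at(1.0 + rel_step) - q_at(1.0 - rel_step)) / (2.0 * rel_step * q0)
    name = getattr(qoi, "name", getattr(qoi, "__name__", "qoi"))
    return SensitivityReport(parameter=parameter, qoi=name, sensitivity=s, rel_step=rel_step)


def sensitivity_sweep(
    params: PduModelParameters,
    growth: GrowthCurve,
    parameter_set="all",
    qoi=peak_external_pald,
    rel_step: float = 0.01,
    **solver_kw,
) -> pd.DataFrame:
    """Sensitivities for a named set, ranked by |S| descending.

    ``parameter_set`` is "all", "morphological", or an iterable of names
    (duplicates rejected).
    """
    if parameter_set == "all":
        names = list(ALL_PARAMETERS)
    elif parameter_set == "morphological":
        names = list(MORPHOLOGICAL_PARAMETERS)
    else:
        names = list(parameter_set)
        if len(set(names)) != len(names):
            raise ParameterError("duplicate parameter names in sweep")
    reports = [
        local_sensitivity(params, growth, n, qoi=qoi, rel_step=rel_step, **solver_kw)
        for n in names
    ]
    df = pd.DataFrame(
        {
            "parameter": [r.parameter for r in reports],
            "qoi": [r.qoi for r in reports],
            "sensitivity": [r.sensitivity for r in reports],
            "rel_step": [r.rel_step for r in reports],
        }
    )
    df["abs_sensitivity"] = df["sensitivity"].abs()
    return df.sort_values("abs_sensitivity", ascending=False, ignore_index=True)
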