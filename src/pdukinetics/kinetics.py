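"""Reaction rate laws, transport fluxes, and the ODE right-hand sides.

The model tracks five metabolites in three well-mixed regions:

* lumen    - interior of the MCPs/MTs (all compartments identical),
* cytosol  - cell interior outside the compartments,
* external - shared growth medium.

PduCDE (1,2-propanediol -> propionaldehyde, irreversible), PduP
(propionaldehyde <-> propionyl-CoA) and PduQ (propionaldehyde <->
1-propanol) act in the lumen; the lumped PduL/PduW step (propionyl-CoA ->
propionate, irreversible) acts in the cytosol.  Metabolites cross the
shell and the cell membrane passively, with a single permeability per
barrier shared by all species.  The external medium is depleted in
proportion to the time-varying cell density, so each cell sees an
identical intracellular state while the medium is shared.

State layout: 15 values, ``[lumen x 5, cytosol x 5, external x 5]`` in
``Species`` order.  The well-mixed variant (broken-compartment limit)
drops the lumen block and uses 10 values.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import ParameterError
from .params import GrowthCurve, PduModelParameters, Species

__all__ = [
    "N_SPECIES",
    "mm_rate",
    "net_reversible_rate",
    "transport_flux",
    "rhs",
    "wellmixed_rhs",
    "initial_state",
    "initial_state_wellmixed",
    "species_totals",
]

logger = logging.getLogger(__name__)

N_SPECIES = len(Species)


def mm_rate(substrate, vmax, km):
    """Michaelis-Menten rate vmax*S/(km+S), in mM/h.

    Negative substrate values (integrator transients) are clamped to 0.
    """
    if km <= 0:
        raise ParameterError("km must be positive")
    s = np.maximum(substrate, 0.0)
    return vmax * s / (km + s)


def net_reversible_rate(fwd_substrate, rev_substrate, kin):
    """Net forward rate of a reversible Michaelis-Menten step (mM/h)."""
    fwd = mm_rate(fwd_substrate, kin.vmax_fwd, kin.km_fwd)
    if kin.vmax_rev == 0:
        return fwd
    return fwd - mm_rate(rev_substrate, kin.vmax_rev, kin.km_rev)


def transport_flux(permeability, area, c_out, c_in):
    """Passive flux into a region: permeability*area*(c_out - c_in).

    Units mM*um^3/h (an amount per time); divide by the receiving volume
    to get a concentration rate.
    """
    return permeability * area * (c_out - c_in)


def initial_state(params: PduModelParameters) -> np.ndarray:
    """All-zero state except the initial external 1,2-propanediol."""
    y = np.zeros(3 * N_SPECIES)
    y[2 * N_SPECIES + Species.PDO] = params.initial_external_pdo
    return y


def initial_state_wellmixed(params: PduModelParameters) -> np.ndarray:
    y = np.zeros(2 * N_SPECIES)
    y[N_SPECIES + Species.PDO] = params.initial_external_pdo
    return y


def _reaction_rates(c_pdo, c_pald, c_pcoa, c_poh, enzymes, vmax_scale):
    """Net lumen-enzyme rates (R_CDE, R_P, R_Q) at given concentrations."""
    cde = enzymes["PduCDE"]
    p = enzymes["PduP"]
    q = enzymes["PduQ"]
    r_cde = mm_rate(c_pdo, vmax_scale * cde.vmax_fwd, cde.km_fwd)
    r_p = mm_rate(c_pald, vmax_scale * p.vmax_fwd, p.km_fwd) - mm_rate(
        c_pcoa, vmax_scale * p.vmax_rev, p.km_rev
    )
    r_q = mm_rate(c_pald, vmax_scale * q.vmax_fwd, q.km_fwd) - mm_rate(
        c_poh, vmax_scale * q.vmax_rev, q.km_rev
    )
    return r_cde, r_p, r_q


def rhs(t, state, params: PduModelParameters, growth: GrowthCurve) -> np.ndarray:
    """Time derivative of the 15-component three-region state (mM/h)."""
    n = N_SPECIES
    lum = state[:n]
    cyt = state[n : 2 * n]
    ext = state[2 * n :]

    ens = params.compartments
    v_comp = ens.total_volume  # um^3, all compartments of one cell
    v_cyt = params.cytosol_volume
    g_shell = params.effective_shell_conductance  # k_c * A_eff, um^3/h
    g_mem = params.membrane_permeability * params.cell.membrane_area
    rho = growth.density_per_um3(t)  # cells per um^3 of medium

    dlum = np.empty(n)
    dcyt = np.empty(n)
    dext = np.empty(n)

    # transport (per-species, identical permeability)
    shell = g_shell * (cyt - lum)  # amount/h into the whole lumen pool
    mem = g_mem * (ext - cyt)  # amount/h into the cytosol
    dlum[:] = shell / v_comp
    dcyt[:] = (-shell + mem) / v_cyt
    dext[:] = -rho * mem

    # lumen reactions (PduCDE, PduP, PduQ)
    scale = params.lumen_vmax_scale()
    r_cde, r_p, r_q = _reaction_rates(
        lum[Species.PDO], lum[Species.PALD], lum[Species.PCOA], lum[Species.POH],
        params.enzymes, scale,
    )
    dlum[Species.PDO] += -r_cde
    dlum[Species.PALD] += r_cde - r_p - r_q
    dlum[Species.PCOA] += r_p
    dlum[Species.POH] += r_q

    # cytosolic lumped PduL/PduW step
    lw = params.enzymes["PduLW"]
    r_lw = mm_rate(cyt[Species.PCOA], lw.vmax_fwd, lw.km_fwd)
    dcyt[Species.PCOA] += -r_lw
    dcyt[Species.PROP] += r_lw

    return np.concatenate((dlum, dcyt, dext))


def wellmixed_rhs(t, state, params: PduModelParameters, growth: GrowthCurve) -> np.ndarray:
    """Broken-compartment model: lumen enzymes act in the whole cell.

    The 10-component state is ``[cell x 5, external x 5]``.  The reacting
    volume is the cytosol plus the (now barrier-free) compartment volume,
    and lumen vmax values are rescaled so total enzyme per cell is
    unchanged.  This is the k_c -> infinity limit of :func:`rhs` and the
    model of the dPduA PduJ control strain.
    """
    n = N_SPECIES
    cyt = state[:n]
    ext = state[n:]

    v_cell = params.cytosol_volume + params.compartments.total_volume
    g_mem = params.membrane_permeability * params.cell.membrane_area
    rho = growth.density_per_um3(t)

    mem = g_mem * (ext - cyt)
    dcyt = mem / v_cell
    dext = -rho * mem

    # lumen enzymes redistributed over the whole cell volume
    if params.enzyme_scaling_mode == "fixed_total_enzyme":
        ref = params.reference_lumen_volume
        if ref is None:
            ref = params.compartments.total_volume
        scale = ref / v_cell
    else:
        scale = params.compartments.total_volume / v_cell
    r_cde, r_p, r_q = _reaction_rates(
        cyt[Species.PDO], cyt[Species.PALD], cyt[Species.PCOA], cyt[Species.POH],
        params.enzymes, scale,
    )
    # PduL/PduW total per cell is also conserved when its volume grows
    lw = params.enzymes["PduLW"]
    lw_scale = params.cytosol_volume / v_cell
    r_lw = mm_rate(cyt[Species.PCOA], lw_scale * lw.vmax_fwd, lw.km_fwd)

    dcyt = dcyt.copy()
    dcyt[Species.PDO] += -r_cde
    dcyt[Species.PALD] += r_cde - r_p - r_q
    dcyt[Species.PCOA] += r_p - r_lw
    dcyt[Species.POH] += r_q
    dcyt[Species.PROP] += r_lw

    return np.concatenate((dcyt, dext))


def species_totals(state, params: PduModelParameters, rho_per_um3) -> np.ndarray:
    """Volume- and cell-number-weighted total of each species.

    Returns, per species, the amount per um^3 of medium (mM-equivalent):
    rho*(V_comp*c_lumen + V_cyt*c_cytosol) + c_external.  With a constant
    cell density and all vmax = 0 this is conserved exactly; the sum over
    species is the carbon-skeleton total (every reaction is 1:1).
    """
    n = N_SPECIES
    state = np.asarray(state)
    if state.shape[-1] == 3 * n:
        lum, cyt, ext = state[..., :n], state[..., n : 2 * n], state[..., 2 * n :]
        v_comp = params.compartments.total_volume
        return rho_per_um3 * (v_comp * lum + params.cytosol_volume * cyt) + ext
    cyt, ext = state[..., :n], state[..., n:]
    v_cell = params.cytosol_volume + params.compartments.total_volume
    return rho_per_um3 * v_cell * cyt + ext
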