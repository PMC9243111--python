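"""Compartment and cell geometry.

The kinetic model sees geometry only through surface areas and volumes:
the shell area over which metabolites diffuse, the encapsulated volume in
which the lumen enzymes act, the cell-membrane area, and the cytosolic
volume.  This module converts shape specifications (spherical
microcompartments, MCPs, or cylindrical microtubes, MTs) into those
quantities and implements the two matching modes used to compare the
geometries: equal total encapsulated volume or equal total shell area.

Canonical internal length unit is the micrometre (um); compartment
dimensions are usually quoted in nanometres, so the constructors take nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ParameterError",
    "CompartmentGeometry",
    "CellGeometry",
    "CompartmentEnsemble",
    "make_sphere",
    "make_cylinder",
    "make_capsule_cell",
    "match_ensemble",
    "sa_v_fold_factor",
    "NM_PER_UM",
]

NM_PER_UM = 1.0e3


class ParameterError(ValueError):
    """Raised for physically inadmissible parameter values."""


@dataclass(frozen=True)
class CompartmentGeometry:
    """Shape and per-unit surface area / volume of one compartment.

    Areas are in um^2, volumes in um^3, lengths in um.  For cylinders the
    transport-relevant area is the lateral surface by default: metabolites
    are assumed to cross the shell along the long axis of the tube and not
    at the ends.  ``area_ends`` holds the two end caps (2*pi*r^2) so that a
    model variant with open ends can apply a separate permeability
    multiplier to them.
    """

    shape: str  # "sphere" | "cylinder"
    radius: float  # um
    length: float = 0.0  # um, cylinders only
    include_end_area: bool = False
    area_per_compartment: float = field(init=False, default=0.0)
    area_lateral: float = field(init=False, default=0.0)
    area_ends: float = field(init=False, default=0.0)
    volume_per_compartment: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder"):
            raise ParameterError(f"unknown compartment shape {self.shape!r}")
        if self.radius <= 0:
            raise ParameterError("compartment radius must be positive")
        r = self.radius
        if self.shape == "sphere":
            lateral = 4.0 * math.pi * r * r
            ends = 0.0
            volume = (4.0 / 3.0) * math.pi * r**3
        else:
            if self.length <= 0:
                raise ParameterError("cylinder length must be positive")
            lateral = 2.0 * math.pi * r * self.length
            ends = 2.0 * math.pi * r * r
            volume = math.pi * r * r * self.length
        area = lateral + (ends if self.include_end_area else 0.0)
        object.__setattr__(self, "area_lateral", lateral)
        object.__setattr__(self, "area_ends", ends)
        object.__setattr__(self, "area_per_compartment", area)
        object.__setattr__(self, "volume_per_compartment", volume)


def make_sphere(diameter_nm: float) -> CompartmentGeometry:
    """Spherical MCP from its diameter in nm (e.g. 140 nm)."""
    if diameter_nm <= 0:
        raise ParameterError("sphere diameter must be positive")
    return CompartmentGeometry(shape="sphere", radius=diameter_nm / (2 * NM_PER_UM))


def make_cylinder(
    diameter_nm: float, length_nm: float, include_end_area: bool = False
) -> CompartmentGeometry:
    """Cylindrical MT from diameter and length in nm (e.g. 50 nm x 2500 nm)."""
    if diameter_nm <= 0 or length_nm <= 0:
        raise ParameterError("cylinder dimensions must be positive")
    return CompartmentGeometry(
        shape="cylinder",
        radius=diameter_nm / (2 * NM_PER_UM),
        length=length_nm / NM_PER_UM,
        include_end_area=include_end_area,
    )


@dataclass(frozen=True)
class CellGeometry:
    """Capsule-shaped cell: a cylinder of radius r capped by two hemispheres.

    ``capsule_radius`` and ``cell_length`` (total, pole to pole) are in um.
    ``cytosol_volume`` is the cell volume minus the total compartment
    volume and is computed by :class:`CompartmentEnsemble`.
    """

    capsule_radius: float  # um
    cell_length: float  # um
    membrane_area: float = field(init=False, default=0.0)
    cell_volume: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        r, L = self.capsule_radius, self.cell_length
        if r <= 0 or L <= 0:
            raise ParameterError("cell dimensions must be positive")
        if L < 2 * r:
            raise ParameterError("capsule length must be at least its diameter")
        body = L - 2 * r
        object.__setattr__(
            self, "membrane_area", 2 * math.pi * r * body + 4 * math.pi * r * r
        )
        object.__setattr__(
            self,
            "cell_volume",
            math.pi * r * r * body + (4.0 / 3.0) * math.pi * r**3,
        )


def make_capsule_cell(radius_um: float = 0.5, length_um: float = 2.5) -> CellGeometry:
    """Default rod cell: 2.5 um long capsule with 0.5 um half-width."""
    return CellGeometry(capsule_radius=radius_um, cell_length=length_um)


@dataclass(frozen=True)
class CompartmentEnsemble:
    """A per-cell population of identical compartments.

    ``count`` may be fractional: the model is a deterministic continuum
    description and the matching modes below do not generally yield
    integer counts.
    """

    geometry: CompartmentGeometry
    count: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParameterError("compartment count must be nonnegative")

    @property
    def total_area(self) -> float:
        return self.count * self.geometry.area_per_compartment

    @property
    def total_area_lateral(self) -> float:
        return self.count * self.geometry.area_lateral

    @property
    def total_area_ends(self) -> float:
        return self.count * self.geometry.area_ends

    @property
    def total_volume(self) -> float:
        return self.count * self.geometry.volume_per_compartment


def match_ensemble(
    base: CompartmentEnsemble,
    target_geom: CompartmentGeometry,
    mode: str,
    count: float | None = None,
) -> CompartmentEnsemble:
    """Build an ensemble of ``target_geom`` compartments matched to ``base``.

    mode = "equal_volume": the returned ensemble has the same total
    encapsulated volume as ``base`` (enzyme concentration is then
    unchanged at fixed total enzyme).
    mode = "equal_area": same total shell area as ``base`` (the smaller
    total volume then concentrates the enzymes).
    mode = "fixed_count": use ``count`` directly.
    """
    if base.total_area <= 0 or base.total_volume <= 0:
        raise ParameterError("base ensemble must have positive totals")
    if mode == "equal_volume":
        n = base.total_volume / target_geom.volume_per_compartment
    elif mode == "equal_area":
        n = base.total_area / target_geom.area_per_compartment
    elif mode == "fixed_count":
        if count is None:
            raise ParameterError("fixed_count mode requires a count")
        n = count
    else:
        raise ParameterError(f"unknown matching mode {mode!r}")
    return CompartmentEnsemble(geometry=target_geom, count=n)


def sa_v_fold_factor(sphere_radius: float, cylinder_radius: float) -> float:
    """Closed-form area fold-change for equal-volume sphere->cylinder matching.

    A sphere has volume-to-area ratio r_s/3 and a lateral-only cylinder
    r_c/2, so matching total volume changes total area by
    (r_s/3)/(r_c/2) = 2 r_s / (3 r_c).  With the printed dimensions
    (140 nm spheres, 50 nm cylinders) this is 1.87, reported as 1.9.
    """
    if sphere_radius <= 0 or cylinder_radius <= 0:
        raise ParameterError("radii must be positive")
    return 2.0 * sphere_radius / (3.0 * cylinder_radius)
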