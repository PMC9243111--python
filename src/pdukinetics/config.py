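"""Configuration parsing and CSV serialization.

One structured YAML dialect configures runs; every physical quantity
carries its unit in the key name (diameter_nm, td_early_h, ...) to
prevent silent unit bugs.  Unknown keys are rejected with the offending
location in the message, and every default filled in is logged with its
provenance (printed in the study vs design default of this package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    CompartmentEnsemble,
    ParameterError,
    make_capsule_cell,
    make_cylinder,
    make_sphere,
    match_ensemble,
)
from .params import (
    DEFAULT_VALUES,
    GrowthCurve,
    PduModelParameters,
    default_enzymes,
    default_parameters,
    parameter_manifest,
)
from .synth import GrowthModel

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_timeseries",
    "read_timeseries",
    "write_growth",
    "read_growth",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration file violates the schema; message names the key."""


_SCHEMA = {
    "geometry": {
        "shape", "diameter_nm", "length_um", "count", "match_mode",
        "include_end_area",
    },
    "cell": {"radius_um", "length_um"},
    "kinetics": {
        k for k in DEFAULT_VALUES
        if k.startswith(("vmax_", "km_"))
    },
    "permeabilities": {"shell_um_h", "membrane_um_h", "end_multiplier"},
    "growth": {"file", "generator"},
    "solver": {"rtol", "atol", "output_grid_h", "t_end_h", "method"},
    "initial_external_pdo_mM": None,
    "enzyme_scaling_mode": None,
    "scenarios": None,
    "output_dir": None,
    "seed": None,
}
_GROWTH_GENERATOR_KEYS = {"n0_per_ml", "lag_h", "td_early_h", "t_switch_h", "td_late_h"}
_SCENARIOS = {"base", "equal_volume", "equal_area", "wellmixed", "open_ends"}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    params: PduModelParameters
    growth_file: Path | None
    growth_model: GrowthModel | None
    scenarios: list
    solver: dict = field(default_factory=dict)
    output_dir: Path = Path("out")
    seed: int = 0

    def growth_curve(self) -> GrowthCurve:
        from .synth import generate_growth_curve

        if self.growth_file is not None:
            return read_growth(self.growth_file)
        return generate_growth_curve(self.growth_model or GrowthModel())


def _require_number(value, key, minimum=None, strict=False):
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{key}: expected a number, got {value!r}")
    if minimum is not None:
        if strict and value <= minimum:
            raise ConfigError(f"{key}: must be > {minimum}, got {value}")
        if not strict and value < minimum:
            raise ConfigError(f"{key}: must be >= {minimum}, got {value}")
    return float(value)


def _check_keys(mapping, allowed, where):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _SCHEMA, str(path))
    for section, keys in _SCHEMA.items():
        if keys is not None and section in raw:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"{section}: expected a mapping")
            _check_keys(raw[section], keys, section)

    defaults_used = []

    def fill(section, key, default_key=None, minimum=None, strict=False):
        block = raw.get(section, {})
        if key in block:
            return _require_number(block[key], f"{section}.{key}", minimum, strict)
        dk = default_key or key
        defaults_used.append(dk)
        return DEFAULT_VALUES[dk]

    # cell
    cell = make_capsule_cell(
        fill("cell", "radius_um", "cell_radius_um", 0, True),
        fill("cell", "length_um", "cell_length_um", 0, True),
    )

    # kinetics
    kin_block = raw.get("kinetics", {})
    overrides = {}
    for k in sorted(_SCHEMA["kinetics"]):
        if k in kin_block:
            overrides[k] = _require_number(kin_block[k], f"kinetics.{k}", 0)
        else:
            defaults_used.append(k)
    enzymes = default_enzymes(overrides)

    # permeabilities
    k_c = fill("permeabilities", "shell_um_h", "shell_permeability_um_h", 0)
    k_m = fill("permeabilities", "membrane_um_h", "membrane_permeability_um_h", 0)
    end_mult = fill("permeabilities", "end_multiplier", "end_permeability_multiplier", 0)

    # geometry
    geo = raw.get("geometry", {})
    shape = geo.get("shape", "sphere")
    if shape not in ("sphere", "cylinder"):
        raise ConfigError(f"geometry.shape: unknown shape {shape!r}")
    base_sphere = make_sphere(DEFAULT_VALUES["mcp_diameter_nm"])
    base_ens = CompartmentEnsemble(base_sphere, DEFAULT_VALUES["mcps_per_cell"])
    if shape == "sphere":
        d = fill("geometry", "diameter_nm", "mcp_diameter_nm", 0, True)
        geom = make_sphere(d)
        count = _require_number(geo.get("count", DEFAULT_VALUES["mcps_per_cell"]),
                                "geometry.count", 0)
        ensemble = CompartmentEnsemble(geom, count)
    else:
        d = fill("geometry", "diameter_nm", "mt_diameter_nm", 0, True)
        length_um = geo.get("length_um", cell.cell_length)
        length_um = _require_number(length_um, "geometry.length_um", 0, True)
        geom = make_cylinder(d, length_um * 1e3, bool(geo.get("include_end_area", False)))
        if "match_mode" in geo:
            mode = geo["match_mode"]
            if mode not in ("equal_volume", "equal_area"):
                raise ConfigError(f"geometry.match_mode: unknown mode {mode!r}")
            ensemble = match_ensemble(base_ens, geom, mode)
        elif "count" in geo:
            ensemble = CompartmentEnsemble(
                geom, _require_number(geo["count"], "geometry.count", 0)
            )
        else:
            raise ConfigError("geometry: cylinders need either count or match_mode")

    pdo0 = raw.get("initial_external_pdo_mM", DEFAULT_VALUES["initial_external_pdo_mM"])
    pdo0 = _require_number(pdo0, "initial_external_pdo_mM", 0)
    if "initial_external_pdo_mM" not in raw:
        defaults_used.append("initial_external_pdo_mM")

    mode = raw.get("enzyme_scaling_mode", "fixed_total_enzyme")
    try:
        params = PduModelParameters(
            compartments=ensemble,
            cell=cell,
            enzymes=enzymes,
            shell_permeability=k_c,
            membrane_permeability=k_m,
            end_permeability_multiplier=end_mult,
            initial_external_pdo=pdo0,
            enzyme_scaling_mode=mode,
            reference_lumen_volume=base_ens.total_volume,
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc

    # growth
    growth_file = None
    growth_model = None
    g = raw.get("growth", {})
    if "file" in g:
        growth_file = path.parent / g["file"]
    else:
        gen = g.get("generator", {}) or {}
        if not isinstance(gen, dict):
            raise ConfigError("growth.generator: expected a mapping")
        _check_keys(gen, _GROWTH_GENERATOR_KEYS, "growth.generator")
        kw = {}
        for yk, attr in [("n0_per_ml", "n0"), ("lag_h", "lag"),
                         ("td_early_h", "td_early"), ("t_switch_h", "t_switch"),
                         ("td_late_h", "td_late")]:
            if yk in gen:
                kw[attr] = _require_number(gen[yk], f"growth.generator.{yk}", 0, True)
        growth_model = GrowthModel(**kw)

    scenarios = raw.get("scenarios", ["base"])
    if not isinstance(scenarios, list) or not set(scenarios) <= _SCENARIOS:
        raise ConfigError(f"scenarios: must be a list drawn from {sorted(_SCENARIOS)}")

    solver = dict(raw.get("solver", {}))

    manifest = {m["key"]: m for m in parameter_manifest()}
    for key in defaults_used:
        prov = manifest.get(key, {}).get("provenance", "default")
        logger.info("config %s: %s = %r filled from defaults (%s)", path, key,
                    DEFAULT_VALUES.get(key), prov)

    return RunConfig(
        params=params,
        growth_file=growth_file,
        growth_model=growth_model,
        scenarios=list(scenarios),
        solver=solver,
        output_dir=Path(raw.get("output_dir", "out")),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# CSV serialization (tidy tables, full float precision, round-trip exact)
# ---------------------------------------------------------------------------

TIMESERIES_COLUMNS = ["time_h", "region", "species", "concentration_mM"]


def write_timeseries(obj, path) -> Path:
    """Write a SimulationResult or tidy DataFrame as tidy CSV."""
    df = obj.to_frame() if hasattr(obj, "to_frame") else pd.DataFrame(obj)
    missing = [c for c in ("time_h", "species", "concentration_mM") if c not in df.columns]
    if missing:
        raise ParameterError(f"time series table lacks columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path) -> pd.DataFrame:
    """Read a tidy time-series CSV; malformed cells are located by line."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("time_h", "species", "concentration_mM") if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing column(s) {missing}")
    for col in ("time_h", "concentration_mM"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if df[col].size and converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ParameterError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at line {row + 2}"
            )
        # numpy's strtod is exact; pandas' fast parser can lose the last ulp
        df[col] = df[col].to_numpy(dtype=np.float64) if df[col].size else converted
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return df


def write_growth(growth: GrowthCurve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_h": growth.times, "cell_density_per_ml": growth.cell_density}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_growth(path) -> GrowthCurve:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_h", "cell_density_per_ml"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    return GrowthCurve(df["time_h"].to_numpy(), df["cell_density_per_ml"].to_numpy())
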