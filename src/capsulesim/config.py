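"""Run configuration: schema, validation, unit conversion, presets.

Configurations are YAML with explicit unit suffixes in every key name
(``*_mm``, ``*_s``, ``*_kpa``, ...) because the quantities involved mix
millimetres, kilopascals and dimensionless constants and implicit units
are a known hazard here.  Unknown keys are rejected; validation errors
name the offending key and constraint.  ``load_config`` returns a fully
resolved configuration (all defaults applied) whose dump/reload is
idempotent.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .dynamics import CapsuleModel, SolverSettings
from .forces import DragModel
from .geometry import MM, CapsuleShape
from .stimulation import (DEFAULT_FOOTPRINT_AMPLITUDE,
                          DEFAULT_FOOTPRINT_VARIANCE_CM2, DoseResponseParams,
                          StimulusParams)
from .tissue import (DEFAULT_RELAX_AMPLITUDES_KPA, DEFAULT_RELAX_TAUS_S,
                     TissueParams)

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config",
           "preset_config", "PRESET_NAMES"]

PRESET_NAMES = ("type1", "type2", "type3")


class ConfigError(ValueError):
    """A configuration file failed validation (names key and constraint)."""


# schema: block -> key -> (required, default)
_SCHEMA = {
    "shape": {
        "r_mm": (True, None),
        "R_mm": (True, None),
        "alpha_per_mm": (True, None),
        "L_mm": (True, None),
    },
    "tissue": {
        "d0_mm": (True, None),
        "h_mm": (True, None),
        "mu": (False, 0.1),
        "relax_amplitudes_kpa": (False, list(DEFAULT_RELAX_AMPLITUDES_KPA)),
        "relax_taus_s": (False, list(DEFAULT_RELAX_TAUS_S)),
        "stress_scale": (False, 1.0),
        "tau_s_s": (False, 17.3),
        "strain_mode": (False, "diameter_ratio"),
        "relaxation_mode": (False, "measured"),
    },
    "stimulus": {
        "amplitude_v": (False, 6.0),
        "frequency_hz": (False, 10.0),
        "pulse_ms": (False, 5.0),
        "electrode_offset_mm": (False, 5.0),
        "footprint_variance_cm2": (False, DEFAULT_FOOTPRINT_VARIANCE_CM2),
        "footprint_amplitude": (False, DEFAULT_FOOTPRINT_AMPLITUDE),
    },
    "dose_response": {
        "freq_slope_kpa_per_hz": (False, 0.24),
        "intercept_kpa": (False, 1.18),
        "half_amplitude_v": (False, 4.97),
        "hill_exponent": (False, 3.72),
        "grouping": (False, "ratio"),
    },
    "drag": {
        "mode": (False, "constant"),
        "b_mn_s_per_mm": (False, None),
        "fluid_viscosity_pa_s": (False, None),
        "film_thickness_mm": (False, None),
    },
    "solver": {
        "dt_s": (False, 0.001),
        "duration_s": (False, 60.0),
        "grid_dx_mm": (False, 0.25),
        "decimation": (False, 10),
        "quad_points": (False, 501),
        "tau_fall_s": (False, None),
        "hold_position": (False, False),
    },
    "output": {
        "trace_path": (False, None),
        "summary_path": (False, None),
    },
}
_TOP_LEVEL = {"schema_version": (False, 1), "mass_g": (True, None)}


def _validate_block(name, block, schema):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"block '{name}' must be a mapping")
    unknown = set(block) - set(schema)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in block '{name}'")
    resolved = {}
    for key, (required, default) in schema.items():
        if key in block:
            resolved[key] = block[key]
        elif required:
            raise ConfigError(f"missing required key '{name}.{key}'")
        else:
            resolved[key] = copy.deepcopy(default)
    return resolved


def resolve(raw: dict) -> dict:
    """Validate a raw config mapping and fill in documented defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SCHEMA) - set(_TOP_LEVEL)
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    resolved = {}
    for key, (required, default) in _TOP_LEVEL.items():
        if key in raw:
            resolved[key] = raw[key]
        elif required:
            raise ConfigError(f"missing required key '{key}'")
        else:
            resolved[key] = default
    if not isinstance(resolved["mass_g"], (int, float)) or resolved["mass_g"] <= 0:
        raise ConfigError("'mass_g' must be a positive number")
    for name, schema in _SCHEMA.items():
        resolved[name] = _validate_block(name, raw.get(name), schema)
    drag = resolved["drag"]
    if drag["mode"] not in ("constant", "surrogate"):
        raise ConfigError("'drag.mode' must be 'constant' or 'surrogate'")
    if drag["mode"] == "constant" and drag["b_mn_s_per_mm"] is None:
        raise ConfigError("'drag.b_mn_s_per_mm' is required in constant mode")
    if drag["mode"] == "surrogate" and (
            drag["fluid_viscosity_pa_s"] is None
            or drag["film_thickness_mm"] is None):
        raise ConfigError("'drag.fluid_viscosity_pa_s' and "
                          "'drag.film_thickness_mm' are required in "
                          "surrogate mode")
    return resolved


@dataclass
class RunConfig:
    """A validated, unit-normalised run configuration.

    ``raw`` is the resolved mapping (config-file units, defaults filled);
    the typed component attributes are SI.
    """

    raw: dict
    shape: CapsuleShape = field(init=False)
    tissue: TissueParams = field(init=False)
    stimulus: StimulusParams = field(init=False)
    dose: DoseResponseParams = field(init=False)
    drag: DragModel = field(init=False)
    solver: SolverSettings = field(init=False)
    mass: float = field(init=False)

    def __post_init__(self):
        raw = self.raw
        try:
            self.shape = CapsuleShape.from_mm(**raw["shape"])
            t = raw["tissue"]
            self.tissue = TissueParams.from_mm(
                d0_mm=t["d0_mm"], h_mm=t["h_mm"], mu=t["mu"],
                relax_amplitudes_kpa=t["relax_amplitudes_kpa"],
                relax_taus=tuple(t["relax_taus_s"]),
                stress_scale=t["stress_scale"], tau_s=t["tau_s_s"],
                strain_mode=t["strain_mode"],
                relaxation_mode=t["relaxation_mode"])
            s = raw["stimulus"]
            self.stimulus = StimulusParams.from_config_units(
                amplitude_v=s["amplitude_v"], frequency_hz=s["frequency_hz"],
                pulse_ms=s["pulse_ms"],
                electrode_offset_mm=s["electrode_offset_mm"],
                footprint_variance_cm2=s["footprint_variance_cm2"],
                footprint_amplitude=s["footprint_amplitude"])
            d = raw["dose_response"]
            self.dose = DoseResponseParams(
                freq_slope=d["freq_slope_kpa_per_hz"],
                intercept=d["intercept_kpa"],
                half_amplitude=d["half_amplitude_v"],
                hill_exponent=d["hill_exponent"])
            dr = raw["drag"]
            if dr["mode"] == "constant":
                # 1 mN s/mm == 1 N s/m
                self.drag = DragModel.constant(float(dr["b_mn_s_per_mm"]))
            else:
                self.drag = DragModel.surrogate(
                    self.shape, viscosity=dr["fluid_viscosity_pa_s"],
                    film_thickness=dr["film_thickness_mm"] * MM)
            so = raw["solver"]
            self.solver = SolverSettings(
                dt=so["dt_s"], grid_dx=so["grid_dx_mm"] * MM,
                decimation=int(so["decimation"]),
                quad_points=int(so["quad_points"]),
                tau_fall=so["tau_fall_s"],
                hold_position=bool(so["hold_position"]))
            self.mass = raw["mass_g"] * 1e-3
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @property
    def duration(self) -> float:
        return float(self.raw["solver"]["duration_s"])

    @property
    def grouping(self) -> str:
        return self.raw["dose_response"]["grouping"]

    def build_model(self, **overrides) -> CapsuleModel:
        kw = dict(shape=self.shape, tissue=self.tissue,
                  stimulus=self.stimulus, drag=self.drag, mass=self.mass,
                  dose=self.dose, solver=self.solver,
                  grouping=self.grouping)
        kw.update(overrides)
        return CapsuleModel(**kw)

    def replace(self, **block_updates) -> "RunConfig":
        """New config with updated keys, e.g. ``replace(shape={'r_mm': 2})``."""
        raw = copy.deepcopy(self.raw)
        for block, updates in block_updates.items():
            if isinstance(updates, dict):
                raw.setdefault(block, {}).update(updates)
            else:
                raw[block] = updates
        return RunConfig(resolve(raw))

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load, validate and unit-normalise a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(resolve(raw))


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved configuration; load(dump(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)


def preset_config(name: str) -> RunConfig:
    """Bundled default configuration for capsule presets type1/type2/type3.

    All three share an 11 mm maximum diameter (R = 5.5 mm) and slope
    0.3/mm; they differ in tip radius: type1 r = 3 mm, type2 r = 2 mm,
    type3 r = 4 mm (the control that should not move).
    """
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("capsulesim") / "configs" / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return RunConfig(resolve(raw))
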