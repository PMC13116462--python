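"""Physical constants, geometry/material/drive parameters, and unit conversions.

All internal computation is strict SI (m, S/m, F, V, Hz, W/m^3, J/m^3).
The micro-units customary in the plasma-treatment literature (uW/mm^3,
uJ/mm^3, mm, ms, kHz, kVpp) appear only at I/O boundaries, through the
conversion helpers defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = [
    "EPSILON_0",
    "GeometryConfig",
    "MaterialConfig",
    "DriveConfig",
    "convert_power_density",
    "convert_energy_density",
    "load_config",
    "default_configs",
]

#: Vacuum permittivity (F/m), CODATA 2018.
EPSILON_0 = 8.8541878128e-12


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of one well of a 96-well plate under treatment.

    Defaults: 6.4 mm well diameter, 0.5 mm needle-electrode gap
    (informational only), 0.1 mm buffer-solution height, 10 um cell-layer
    height, 7.5 nm membrane thickness, 1.5 mm dish-bottom height.
    All lengths in metres.
    """

    well_radius: float = 3.2e-3
    electrode_gap: float = 0.5e-3
    buffer_height: float = 0.1e-3
    cell_height: float = 10e-6
    membrane_thickness: float = 7.5e-9
    dish_height: float = 1.5e-3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ConfigError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.membrane_thickness < self.cell_height:
            raise ConfigError(
                "membrane_thickness must be smaller than cell_height "
                f"({self.membrane_thickness} >= {self.cell_height})"
            )


@dataclass(frozen=True)
class MaterialConfig:
    """Electrical material properties of cytoplasm, membrane, buffer and dish.

    Permittivities are stored as relative values; absolute permittivities
    (F/m) are exposed as properties.  The cell membrane's permittivity is
    not tabulated with the other constants of this system and defaults to
    a typical lipid-bilayer value (relative permittivity 5, configurable);
    an intact membrane is treated as a perfect dielectric (conductivity 0).
    """

    cytoplasm_rel_permittivity: float = 30.0
    cytoplasm_conductivity: float = 1.0
    buffer_conductivity: float = 0.172
    dish_rel_permittivity: float = 2.4
    membrane_rel_permittivity: float = 5.0
    membrane_conductivity: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "cytoplasm_rel_permittivity",
            "dish_rel_permittivity",
            "membrane_rel_permittivity",
        ):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be strictly positive")
        for name in (
            "cytoplasm_conductivity",
            "buffer_conductivity",
            "membrane_conductivity",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def cytoplasm_permittivity(self) -> float:
        return self.cytoplasm_rel_permittivity * EPSILON_0

    @property
    def dish_permittivity(self) -> float:
        return self.dish_rel_permittivity * EPSILON_0

    @property
    def membrane_permittivity(self) -> float:
        return self.membrane_rel_permittivity * EPSILON_0


@dataclass(frozen=True)
class DriveConfig:
    """Sinusoidal high-voltage drive: v(t) = amplitude * sin(2*pi*f*t + phase).

    Defaults: 20 kHz, 20 kV peak-to-peak (amplitude 10 kV), phase 0 at
    treatment onset.  The phase reference at onset is a modelling choice
    and is configurable.
    """

    frequency: float = 20e3
    peak_to_peak_voltage: float = 20e3
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.frequency > 0):
            raise ConfigError("frequency must be strictly positive")
        if self.peak_to_peak_voltage < 0:
            raise ConfigError("peak_to_peak_voltage must be non-negative")

    @property
    def amplitude(self) -> float:
        """Voltage amplitude (V), exactly half the peak-to-peak value."""
        return self.peak_to_peak_voltage / 2.0

    @property
    def omega(self) -> float:
        """Angular frequency (rad/s)."""
        import math

        return 2.0 * math.pi * self.frequency

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

# Scale factors to SI (W/m^3 resp. J/m^3).  1 uW/mm^3 = 1e-6 W / 1e-9 m^3.
_POWER_DENSITY_TO_SI = {
    "W/m^3": 1.0,
    "uW/mm^3": 1e3,
}
_ENERGY_DENSITY_TO_SI = {
    "J/m^3": 1.0,
    "J/mm^3": 1e9,
    "uJ/mm^3": 1e3,
}

_UNIT_ALIASES = {
    "w/m3": "W/m^3",
    "w/m^3": "W/m^3",
    "uw/mm3": "uW/mm^3",
    "uw/mm^3": "uW/mm^3",
    "μw/mm3": "uW/mm^3",
    "μw/mm^3": "uW/mm^3",
    "j/m3": "J/m^3",
    "j/m^3": "J/m^3",
    "j/mm3": "J/mm^3",
    "j/mm^3": "J/mm^3",
    "uj/mm3": "uJ/mm^3",
    "uj/mm^3": "uJ/mm^3",
    "μj/mm3": "uJ/mm^3",
    "μj/mm^3": "uJ/mm^3",
}


def _canonical_unit(unit: str, table: dict) -> str:
    key = _UNIT_ALIASES.get(unit.strip().lower(), unit)
    if key not in table:
        raise ConfigError(
            f"unknown unit {unit!r}; supported: {sorted(table)}"
        )
    return key


def convert_power_density(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a volumetric power density between W/m^3 and uW/mm^3."""
    src = _canonical_unit(from_unit, _POWER_DENSITY_TO_SI)
    dst = _canonical_unit(to_unit, _POWER_DENSITY_TO_SI)
    return value * (_POWER_DENSITY_TO_SI[src] / _POWER_DENSITY_TO_SI[dst])


def convert_energy_density(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a volumetric energy density between J/m^3, J/mm^3 and uJ/mm^3."""
    src = _canonical_unit(from_unit, _ENERGY_DENSITY_TO_SI)
    dst = _canonical_unit(to_unit, _ENERGY_DENSITY_TO_SI)
    return value * (_ENERGY_DENSITY_TO_SI[src] / _ENERGY_DENSITY_TO_SI[dst])


# ---------------------------------------------------------------------------
# Config-file loading
# ---------------------------------------------------------------------------

# File keys are in the reporting units of the experimental literature
# (mm, um, nm, S/m, kHz, kVpp); each maps to (section, SI field, scale).
_GEOMETRY_KEYS = {
    "well_diameter_mm": ("well_radius", 0.5e-3),
    "well_radius_mm": ("well_radius", 1e-3),
    "electrode_gap_mm": ("electrode_gap", 1e-3),
    "buffer_height_mm": ("buffer_height", 1e-3),
    "cell_height_um": ("cell_height", 1e-6),
    "membrane_thickness_nm": ("membrane_thickness", 1e-9),
    "dish_height_mm": ("dish_height", 1e-3),
}
_MATERIAL_KEYS = {
    "cytoplasm_rel_permittivity": ("cytoplasm_rel_permittivity", 1.0),
    "cytoplasm_conductivity_S_m": ("cytoplasm_conductivity", 1.0),
    "buffer_conductivity_S_m": ("buffer_conductivity", 1.0),
    "dish_rel_permittivity": ("dish_rel_permittivity", 1.0),
    "membrane_rel_permittivity": ("membrane_rel_permittivity", 1.0),
    "membrane_conductivity_S_m": ("membrane_conductivity", 1.0),
}
_DRIVE_KEYS = {
    "frequency_khz": ("frequency", 1e3),
    "peak_to_peak_kv": ("peak_to_peak_voltage", 1e3),
    "phase_rad": ("phase", 1.0),
}


def _parse_section(data: dict, keymap: dict, cls, section: str):
    overrides = {}
    for key, raw in (data or {}).items():
        if key not in keymap:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        field, scale = keymap[key]
        try:
            overrides[field] = float(raw) * scale
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric value for {key!r}: {raw!r}") from exc
    try:
        return cls(**overrides)
    except ConfigError as exc:
        # re-raise naming the offending file key rather than the SI field
        inverse = {v[0]: k for k, v in keymap.items()}
        msg = str(exc)
        for field, key in inverse.items():
            msg = msg.replace(field, key)
        raise ConfigError(msg) from exc


def default_configs() -> tuple[GeometryConfig, MaterialConfig, DriveConfig]:
    """The default well/material/drive parameter set of this system."""
    return GeometryConfig(), MaterialConfig(), DriveConfig()


def load_config(path) -> tuple[GeometryConfig, MaterialConfig, DriveConfig]:
    """Load a YAML config file; missing keys fall back to the defaults.

    The file has up to three sections (``geometry``, ``materials``,
    ``drive``) whose keys are in reporting units, e.g.::

        geometry:
          well_diameter_mm: 6.4
        drive:
          frequency_khz: 20
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping at top level")
    unknown = set(data) - {"geometry", "materials", "drive"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    geometry = _parse_section(data.get("geometry"), _GEOMETRY_KEYS, GeometryConfig, "geometry")
    materials = _parse_section(data.get("materials"), _MATERIAL_KEYS, MaterialConfig, "materials")
    drive = _parse_section(data.get("drive"), _DRIVE_KEYS, DriveConfig, "drive")
    return geometry, materials, drive
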