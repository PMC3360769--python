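"""Structured text configuration for parameter sets.

A YAML file can supply either the tubulin constants directly, keys::

    lambda_nm: 0.612
    a_um2_per_min: 7.5
    k_um_per_min_per_uM: 1.0
    cc_uM: 11.5
    ct_uM: 25.0
    V_L: 4.0e-12

or, instead of ``V_L``, an egg geometry from which the ectoplasmic
volume is computed::

    egg:
      de_um: 1000.0
      h_um: 5.0
      df_um: 15.0

Supplying both ``V_L`` and ``egg`` is an error (the two prescribe the
volume twice).  Values not present fall back to the chosen preset;
explicit CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .params import EggGeometry, TubulinParameters, ectoplasm_volume, preset

__all__ = ["ConfigError", "load_config", "resolve_parameters"]

_SCALAR_KEYS = {
    "lambda_nm": "lambda_dimer",
    "a_um2_per_min": "a",
    "k_um_per_min_per_uM": "k",
    "cc_uM": "c_c",
    "ct_uM": "c_t",
    "V_L": "V",
}
_EGG_KEYS = {"de_um": "d_e", "h_um": "h", "df_um": "d_f"}


class ConfigError(ValueError):
    """Malformed configuration file."""


def load_config(path: str | Path) -> dict:
    """Parse and validate a YAML config; returns the raw mapping."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_SCALAR_KEYS) - {"egg"}
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "V_L" in data and "egg" in data:
        raise ConfigError(
            f"{path}: keys 'V_L' and 'egg' both prescribe the cytoplasmic "
            "volume; supply only one"
        )
    if "egg" in data:
        egg = data["egg"]
        if not isinstance(egg, dict):
            raise ConfigError(f"{path}: 'egg' must be a mapping")
        bad = set(egg) - set(_EGG_KEYS)
        if bad:
            raise ConfigError(f"{path}: unknown egg keys {sorted(bad)}")
    return data


def resolve_parameters(
    preset_name: str = "generic",
    config: dict | None = None,
    **overrides: float | None,
) -> tuple[TubulinParameters, EggGeometry | None]:
    """Merge preset, config file and explicit overrides into a parameter set.

    Precedence (lowest to highest): named preset, config file, keyword
    overrides (None values ignored).  Overrides use the internal field
    names (lambda_dimer in µm, a, k, c_c, c_t, V).  Returns the
    parameters and the egg geometry when one was specified.
    """
    base = preset(preset_name)
    geometry: EggGeometry | None = None
    if preset_name == "beroe":
        from .params import beroe_geometry
        geometry = beroe_geometry()

    updates: dict[str, float] = {}
    if config:
        for key, fld in _SCALAR_KEYS.items():
            if key in config:
                value = float(config[key])
                if key == "lambda_nm":
                    value *= 1e-3  # nm -> µm
                updates[fld] = value
        if "egg" in config:
            egg_raw = {_EGG_KEYS[k]: float(v) for k, v in config["egg"].items()}
            defaults = {"d_e": 1000.0, "h": 5.0, "d_f": 15.0}
            geometry = EggGeometry(**{**defaults, **egg_raw})
            updates["V"] = ectoplasm_volume(geometry)
    for fld, value in overrides.items():
        if value is None:
            continue
        if fld not in set(_SCALAR_KEYS.values()):
            raise ConfigError(f"unknown parameter override {fld!r}")
        updates[fld] = float(value)
    return (replace(base, **updates) if updates else base), geometry
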