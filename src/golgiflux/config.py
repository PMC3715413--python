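"""TOML configuration loading and saving.

A scenario file holds one ``[parameters]`` table and repeated ``[[species]]``
blocks whose keys match the field names of :class:`ModelParameters` and
:class:`SpeciesSpec` exactly; unknown keys are rejected.  Serializing a
configuration and reloading it reproduces it exactly (floats are written
with ``repr`` round-trip precision).
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional, Sequence

from .core import (
    Boundary,
    ConfigurationError,
    ErAccess,
    ModelParameters,
    Role,
    SpeciesSpec,
    Topology,
    validate,
)

__all__ = ["load_config", "save_config", "dumps_config"]

_PARAM_FIELDS = {
    "n_cisternae": int,
    "period": float,
    "omega": float,
    "n_sites": float,
    "T_ER": float,
    "topology": Topology,
    "boundary": Boundary,
    "er_access": ErAccess,
    "linear_loading": bool,
    "dt": float,
    "tol": float,
    "max_periods": int,
}

_SPECIES_FIELDS = {
    "name": str,
    "role": Role,
    "K": float,
    "kappa": float,
    "C_init": float,
    "site_group": str,
}


def _coerce(key: str, value, typ):
    try:
        if isinstance(typ, type) and issubclass(typ, (Topology, Boundary, ErAccess, Role)):
            return typ(value)
        if typ is bool:
            if not isinstance(value, bool):
                raise ValueError("expected a boolean")
            return value
        if typ is int:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValueError("expected an integer")
            return value
        if typ is float:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError("expected a number")
            return float(value)
        return typ(value)
    except ValueError as exc:
        raise ConfigurationError(f"invalid value for {key!r}: {value!r} ({exc})") from None


def load_config(path) -> tuple[list[SpeciesSpec], ModelParameters]:
    """Read a scenario configuration from a TOML file and validate it."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    unknown_top = set(data) - {"parameters", "species"}
    if unknown_top:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown_top)}")

    raw_params = data.get("parameters", {})
    unknown = set(raw_params) - set(_PARAM_FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown [parameters] keys: {sorted(unknown)}")
    kwargs = {k: _coerce(k, v, _PARAM_FIELDS[k]) for k, v in raw_params.items()}
    params = ModelParameters(**kwargs)

    species = []
    for i, block in enumerate(data.get("species", [])):
        unknown = set(block) - set(_SPECIES_FIELDS)
        if unknown:
            raise ConfigurationError(f"unknown [[species]] keys in block {i + 1}: {sorted(unknown)}")
        missing = {"name", "role", "K"} - set(block)
        if missing:
            raise ConfigurationError(f"[[species]] block {i + 1} missing keys: {sorted(missing)}")
        skw = {k: _coerce(k, v, _SPECIES_FIELDS[k]) for k, v in block.items()}
        species.append(SpeciesSpec(**skw))

    validate(species, params)
    return species, params


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, (Topology, Boundary, ErAccess, Role)):
        return f'"{v.value}"'
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {type(v)}")


def dumps_config(
    species: Sequence[SpeciesSpec],
    params: ModelParameters,
    scenario: Optional[str] = None,
) -> str:
    """Serialize a configuration to TOML text.

    Keys whose preset values are package defaults rather than published
    constants (transport coefficient, site concentration, loss rates) are
    annotated with a trailing comment in the output.
    """
    from .presets import DEFAULT_KEYS

    lines = []
    if scenario:
        lines.append(f"# scenario: {scenario}")
    lines.append("[parameters]")
    p = params
    for key in _PARAM_FIELDS:
        value = getattr(p, key)
        mark = "  # package default" if key in DEFAULT_KEYS else ""
        lines.append(f"{key} = {_toml_value(value)}{mark}")
    for s in species:
        lines.append("")
        lines.append("[[species]]")
        for key in _SPECIES_FIELDS:
            value = getattr(s, key)
            if key == "site_group" and value is None:
                continue
            mark = "  # package default" if key in DEFAULT_KEYS else ""
            lines.append(f"{key} = {_toml_value(value)}{mark}")
    return "\n".join(lines) + "\n"


def save_config(
    species: Sequence[SpeciesSpec],
    params: ModelParameters,
    path,
    scenario: Optional[str] = None,
) -> Path:
    """Write a configuration to a TOML file (round-trips exactly)."""
    path = Path(path)
    path.write_text(dumps_config(species, params, scenario))
    return path
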