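"""Unit-tagged quantity parsing for configuration files.

Internal units are hours (time), h^-1 (rates), grams (cell mass), g L^-1
(glucose), mol L^-1 (enzyme concentrations) and liters (volume).  Config files
must tag every dimensioned quantity with an explicit unit string, e.g.
``"0.15 /h"``, ``"3.6 /d"``, ``"15 pg"``, ``"2 uM"``; dimensionless values may
be bare numbers.
"""

from __future__ import annotations

from .exceptions import ConfigurationError

#: conversion factor from each accepted unit to the internal unit
_FACTORS: dict[str, dict[str, float]] = {
    "rate": {
        "/h": 1.0, "1/h": 1.0, "h^-1": 1.0, "h-1": 1.0,
        "/d": 1 / 24.0, "1/d": 1 / 24.0, "d^-1": 1 / 24.0, "/day": 1 / 24.0,
    },
    "time": {"h": 1.0, "hr": 1.0, "hours": 1.0, "d": 24.0, "day": 24.0,
             "days": 24.0, "min": 1 / 60.0},
    "mass": {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "ng": 1e-9, "pg": 1e-12,
             "fg": 1e-15},
    "mass_conc": {"g/L": 1.0, "mg/L": 1e-3, "ug/L": 1e-6, "g/mL": 1e3},
    "molar": {"M": 1.0, "mol/L": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9},
    "volume": {"L": 1.0, "mL": 1e-3, "uL": 1e-6, "nL": 1e-9},
}

#: canonical internal unit per dimension, used when emitting configs
CANONICAL_UNIT = {
    "rate": "/h", "time": "h", "mass": "g", "mass_conc": "g/L",
    "molar": "M", "volume": "L",
}

_DIMENSIONLESS_TAGS = {"", "-", "1", "dimensionless"}


def parse_quantity(raw, dimension: str, key: str = "value") -> float:
    """Convert a tagged quantity to its internal-unit float value.

    Parameters
    ----------
    raw
        Either a bare number (dimensionless only) or a string
        ``"<number> <unit>"``.
    dimension
        One of ``rate, time, mass, mass_conc, molar, volume, dimensionless``.
    key
        Name used in error messages.
    """
    if dimension == "dimensionless":
        if isinstance(raw, bool):
            raise ConfigurationError(f"{key}: expected a number, got a boolean")
        if isinstance(raw, (int, float)):
            return float(raw)
        value, unit = _split(raw, key)
        if unit not in _DIMENSIONLESS_TAGS:
            raise ConfigurationError(
                f"{key}: unexpected unit {unit!r} on a dimensionless quantity")
        return value

    if dimension not in _FACTORS:
        raise ConfigurationError(f"{key}: unknown dimension {dimension!r}")
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        raise ConfigurationError(
            f"{key}: missing unit tag; write e.g. "
            f"'{raw} {CANONICAL_UNIT[dimension]}'")
    value, unit = _split(raw, key)
    try:
        factor = _FACTORS[dimension][unit]
    except KeyError:
        allowed = ", ".join(sorted(_FACTORS[dimension]))
        raise ConfigurationError(
            f"{key}: unit {unit!r} is not a {dimension} unit "
            f"(allowed: {allowed})") from None
    return value * factor


def format_quantity(value: float, dimension: str) -> str | float:
    """Render an internal-unit value as a tagged string (round-trip safe)."""
    if dimension == "dimensionless":
        return float(value)
    return f"{float(value)!r} {CANONICAL_UNIT[dimension]}"


def _split(raw, key: str) -> tuple[float, str]:
    if not isinstance(raw, str):
        raise ConfigurationError(f"{key}: cannot parse {raw!r} as a quantity")
    parts = raw.strip().split(None, 1)
    try:
        value = float(parts[0])
    except (ValueError, IndexError):
        raise ConfigurationError(
            f"{key}: cannot parse {raw!r} as '<number> <unit>'") from None
    unit = parts[1].strip() if len(parts) > 1 else ""
    return value, unit
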