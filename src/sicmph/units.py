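"""Tiny unit parsing for CLI options: "100 nm", "1 ms", "0.5 um" -> SI."""

from __future__ import annotations

import re

__all__ = ["parse_length", "parse_time", "parse_quantity"]

_LENGTH = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_TIME = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6}

_PATTERN = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]*)\s*$")


def parse_quantity(value, table: dict[str, float], default_unit: str):
    """Parse a number-with-suffix string (or pass a bare number through)."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _PATTERN.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    number, unit = m.groups()
    unit = unit or default_unit
    if unit not in table:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(number) * table[unit]


def parse_length(value) -> float:
    """Length in metres from e.g. '100 nm', '0.5um', 1e-7."""
    return parse_quantity(value, _LENGTH, "m")


def parse_time(value) -> float:
    """Time in seconds from e.g. '1 ms', '200s', 0.001."""
    return parse_quantity(value, _TIME, "s")
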