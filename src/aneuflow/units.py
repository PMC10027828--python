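"""Tiny unit handling for config files.

Internally everything is SI (m, s, Pa, kg/m^3).  Config files may attach a
unit suffix to a number, e.g. ``"3 mm"``, ``"30 cm"`` or ``"0.8 s"``; bare
numbers are taken to be SI already.
"""

from __future__ import annotations

_LENGTH = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6}
_TIME = {"s": 1.0, "ms": 1e-3}
_VOLUME = {"m3": 1.0, "m^3": 1.0, "cm3": 1e-6, "cm^3": 1e-6, "mm3": 1e-9, "mm^3": 1e-9}

_TABLES = {"length": _LENGTH, "time": _TIME, "volume": _VOLUME}


def parse_quantity(value, kind: str = "length") -> float:
    """Convert a config value to SI float.

    Accepts a plain number (assumed SI) or a string ``"<number> <unit>"``
    (space optional).  ``kind`` selects the unit table: ``length``, ``time``
    or ``volume``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot parse quantity from {type(value).__name__}")
    table = _TABLES[kind]
    s = value.strip()
    # split trailing alphabetic unit (possibly with ^3 / 3 suffix for volumes)
    for unit in sorted(table, key=len, reverse=True):
        if s.endswith(unit):
            num = s[: -len(unit)].strip()
            if num:
                try:
                    return float(num) * table[unit]
                except ValueError:
                    break
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"cannot parse {kind} quantity {value!r}") from None
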