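"""Unit handling at the I/O boundary.

Internally the whole package works in SI metres and minutes. Published
anatomical tables mix m/min, mm/s and µm, which is an invitation for silent
unit bugs, so every parameter file key carries a unit suffix
(``capillary_radius_um: 3.4``) that is converted exactly once on entry.
"""

from __future__ import annotations

# conversion factors to the canonical unit of each quantity kind
# (metres, square metres, cubic metres, minutes)
_FACTORS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "mm": 1e-3, "um": 1e-6},
    "area": {"m2": 1.0, "mm2": 1e-6, "um2": 1e-12},
    "volume": {"m3": 1.0, "mm3": 1e-9, "ml": 1e-6, "ul": 1e-9},
    "flow": {"m3_per_min": 1.0, "ml_per_min": 1e-6, "l_per_min": 1e-3},
    "speed": {
        "m_per_min": 1.0,
        "mm_per_min": 1e-3,
        "um_per_min": 1e-6,
        "m_per_s": 60.0,
        "mm_per_s": 60e-3,
        "um_per_s": 60e-6,
    },
    "concentration": {
        "cells_per_m3": 1.0,
        "cells_per_ml": 1e6,
        "cells_per_ul": 1e9,
    },
    "rate": {"per_min": 1.0, "per_hr": 1.0 / 60.0, "per_s": 60.0},
    "count": {"cells": 1.0, "count": 1.0},
    "dimensionless": {"": 1.0},
}


def convert(value: float, unit: str, kind: str) -> float:
    """Convert *value* given in *unit* to the canonical unit for *kind*."""
    try:
        factors = _FACTORS[kind]
    except KeyError:
        raise ValueError(f"unknown quantity kind {kind!r}") from None
    try:
        return value * factors[unit]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r} for quantity kind {kind!r}; "
            f"allowed: {sorted(factors)}"
        ) from None


def allowed_units(kind: str) -> list[str]:
    return sorted(_FACTORS[kind])
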