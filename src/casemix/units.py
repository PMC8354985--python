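"""Time-equivalent unit handling.

All capacities and usages are stored internally in minutes. Files and
reports may use any supported unit; conversion happens at the boundary.
"""

from __future__ import annotations

#: minutes per declared unit
_MINUTES: dict[str, float] = {
    "min": 1.0,
    "minute": 1.0,
    "minutes": 1.0,
    "h": 60.0,
    "hour": 60.0,
    "hours": 60.0,
    "day": 1440.0,
    "days": 1440.0,
    "bed_day": 1440.0,
    "bed_days": 1440.0,
}


def to_minutes(value: float, unit: str) -> float:
    """Convert *value* expressed in *unit* to minutes."""
    try:
        return value * _MINUTES[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(_MINUTES)}") from None


def from_minutes(value: float, unit: str) -> float:
    """Convert *value* in minutes back to *unit*."""
    try:
        return value / _MINUTES[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(_MINUTES)}") from None
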