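"""Minimal unit registry keyed by Unit-Ontology-style CURIEs.

Multicell models at the tissue scale span micrometers to millimeters and
seconds to days, so a handful of length and time units with SI conversion
factors suffices; no external unit ontology is imported.  Units are
identified by ``UO:<name>`` CURIEs and may be written bare (``minute``) in
dialect files.
"""

from __future__ import annotations

from .ontology import Curie

#: unit local name -> (dimension, factor to SI base unit)
_REGISTRY: dict[str, tuple[str, float]] = {
    "meter": ("length", 1.0),
    "millimeter": ("length", 1e-3),
    "micrometer": ("length", 1e-6),
    "nanometer": ("length", 1e-9),
    "second": ("time", 1.0),
    "minute": ("time", 60.0),
    "hour": ("time", 3600.0),
    "day": ("time", 86400.0),
    "dimensionless": ("dimensionless", 1.0),
}


def unit_curie(name: str | Curie) -> Curie:
    """Normalize a unit token (bare name or CURIE) to a ``UO:`` CURIE."""
    if isinstance(name, Curie):
        local = name.local_id
    else:
        local = name.split(":", 1)[1] if ":" in name else name
    if local not in _REGISTRY:
        from .errors import UnitError

        raise UnitError(f"unknown unit {name!r}")
    return Curie("UO", local)


def is_known(name: str | Curie) -> bool:
    try:
        unit_curie(name)
    except Exception:
        return False
    return True


def dimension(unit: str | Curie) -> str:
    return _REGISTRY[unit_curie(unit).local_id][0]


def is_length(unit: str | Curie) -> bool:
    return dimension(unit) == "length"


def is_time(unit: str | Curie) -> bool:
    return dimension(unit) == "time"


def to_si(value: float, unit: str | Curie) -> float:
    return value * _REGISTRY[unit_curie(unit).local_id][1]


def convert(value: float, src: str | Curie, dst: str | Curie) -> float:
    """Convert *value* between two units of the same dimension."""
    s, d = unit_curie(src), unit_curie(dst)
    if dimension(s) != dimension(d):
        from .errors import UnitError

        raise UnitError(f"cannot convert {s} to {d}")
    return value * _REGISTRY[s.local_id][1] / _REGISTRY[d.local_id][1]
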