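"""Anatomical zone taxonomy and label grammar for knee SPECT/CT localization.

The localization scheme partitions the periarticular bones into named zones:
9 femoral (8 condylar quadrant zones plus the femoral-shaft reference zone
``R``), 8 patellar, and 13 tibial zones.  Labels are compact strings such as
``F1sa`` (femur, medial, superior, anterior), ``T4`` (tibial distal plate
area) or ``R`` (reference zone).

Grammar
-------
``<bone><column><vertical?><depth?>``, where

* bone: ``F`` femur, ``T`` tibia, ``P`` patella (``R`` alone denotes the
  femoral reference zone);
* column: ``1`` medial, ``2`` lateral, ``3`` tibial intercondylar area,
  ``4`` distal plate area;
* vertical: ``s`` superior, ``i`` inferior;
* depth: ``a`` anterior, ``p`` posterior.

Validity rules: column 3 and 4 exist only on the tibia; the reference zone
only on the femur; femoral/tibial columns 1-3 carry both vertical and depth
modifiers; ``T4`` and ``R`` carry none; patellar zones carry vertical always
and depth only at the *geometric* level.  The *reportable* level collapses
the two patellar depth sub-zones into a single row (``P1s`` etc.), giving the
25 report rows, with ``R`` kept separate as the normalization reference.

The scheme exists in a *native* and a *postoperative* variant (for knees
after medial opening-wedge high tibial osteotomy).  Both variants share the
identical label set; they differ only in partition geometry (see
:mod:`kneespect.partition`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum, IntEnum

from .errors import InvalidZoneError, ZoneParseError

__all__ = [
    "Bone",
    "Column",
    "Vertical",
    "Depth",
    "SchemeVariant",
    "ZoneID",
    "REFERENCE_ZONE",
    "parse_zone_label",
    "enumerate_zones",
    "reportable_members",
]


class Bone(str, Enum):
    FEMUR = "F"
    TIBIA = "T"
    PATELLA = "P"


class Column(IntEnum):
    REFERENCE = 0
    MEDIAL = 1
    LATERAL = 2
    INTERCONDYLAR = 3
    DISTAL_PLATE = 4


class Vertical(str, Enum):
    SUPERIOR = "s"
    INFERIOR = "i"


class Depth(str, Enum):
    ANTERIOR = "a"
    POSTERIOR = "p"


class SchemeVariant(str, Enum):
    NATIVE = "native"
    POSTOPERATIVE = "postoperative"


def _as_variant(variant: "SchemeVariant | str") -> SchemeVariant:
    try:
        return SchemeVariant(variant)
    except ValueError:
        raise InvalidZoneError(
            f"unknown scheme variant {variant!r}; expected one of "
            f"{[v.value for v in SchemeVariant]}"
        ) from None


@dataclass(frozen=True)
class ZoneID:
    """One anatomical zone of the localization scheme.

    Immutable and hashable; construction validates the per-bone rules, so an
    instance is always a legal zone.  ``str(zone)`` yields the canonical
    label and round-trips through :func:`parse_zone_label`.
    """

    bone: Bone
    column: Column
    vertical: Vertical | None = None
    depth: Depth | None = None

    def __post_init__(self) -> None:
        b, c, v, d = self.bone, self.column, self.vertical, self.depth
        if c == Column.REFERENCE:
            if b != Bone.FEMUR:
                raise ZoneParseError("the reference zone R exists only on the femur")
            if v is not None or d is not None:
                raise ZoneParseError("the reference zone R carries no modifiers")
            return
        if c in (Column.INTERCONDYLAR, Column.DISTAL_PLATE) and b != Bone.TIBIA:
            raise ZoneParseError(
                f"column {int(c)} ({c.name.lower()}) is valid only for the tibia, "
                f"not {b.name.lower()}"
            )
        if c == Column.DISTAL_PLATE:
            if v is not None or d is not None:
                raise ZoneParseError("T4 (distal plate area) carries no modifiers")
            return
        # Remaining: femoral/tibial columns 1-3 and patellar columns 1-2.
        if b == Bone.PATELLA:
            if v is None:
                raise ZoneParseError("patellar zones require a vertical modifier (s/i)")
            return  # depth optional: present = geometric, absent = reportable
        if v is None or d is None:
            raise ZoneParseError(
                f"{b.name.lower()} column-{int(c)} zones require both vertical (s/i) "
                "and depth (a/p) modifiers"
            )

    def render(self) -> str:
        if self.column == Column.REFERENCE:
            return "R"
        s = f"{self.bone.value}{int(self.column)}"
        if self.vertical is not None:
            s += self.vertical.value
        if self.depth is not None:
            s += self.depth.value
        return s

    def __str__(self) -> str:  # pragma: no cover - delegation
        return self.render()


REFERENCE_ZONE = ZoneID(Bone.FEMUR, Column.REFERENCE)

_LABEL_RE = re.compile(r"^([FTP])([1-4])([si])?([ap])?$")


def parse_zone_label(label: str) -> ZoneID:
    """Parse a canonical zone label (e.g. ``"F1sa"``, ``"T4"``, ``"R"``).

    Raises
    ------
    ZoneParseError
        If the label is malformed or violates a per-bone validity rule; the
        message names the violated rule.
    """
    if not isinstance(label, str):
        raise ZoneParseError(f"zone label must be a string, got {type(label).__name__}")
    if label == "R":
        return REFERENCE_ZONE
    m = _LABEL_RE.match(label)
    if m is None:
        raise ZoneParseError(
            f"malformed zone label {label!r}: expected <F|T|P><1-4>[s|i][a|p] or 'R'"
        )
    bone, col, vert, depth = m.groups()
    return ZoneID(
        Bone(bone),
        Column(int(col)),
        Vertical(vert) if vert else None,
        Depth(depth) if depth else None,
    )


def _zones_from_labels(labels: list[str]) -> tuple[ZoneID, ...]:
    return tuple(parse_zone_label(s) for s in labels)


# Geometric zones: every voxel-level zone, in the order used for label-map
# integers.  Tibial columns are ordered 1, 3, 2 within each quadrant block to
# match the report row order (medial, intercondylar, lateral).
_GEOMETRIC_LABELS = (
    ["F1sa", "F2sa", "F1sp", "F2sp", "F1ia", "F2ia", "F1ip", "F2ip", "R"]
    + ["P1sa", "P2sa", "P1sp", "P2sp", "P1ia", "P2ia", "P1ip", "P2ip"]
    + ["T1sa", "T3sa", "T2sa", "T1sp", "T3sp", "T2sp",
       "T1ia", "T3ia", "T2ia", "T1ip", "T3ip", "T2ip", "T4"]
)

# Reportable zones: the 25 uptake-report rows (8 F + 4 P + 13 T); the
# reference zone is reported separately as the normalization denominator.
_REPORTABLE_LABELS = (
    ["F1sa", "F2sa", "F1sp", "F2sp", "F1ia", "F2ia", "F1ip", "F2ip"]
    + ["P1s", "P2s", "P1i", "P2i"]
    + ["T1sa", "T3sa", "T2sa", "T1sp", "T3sp", "T2sp",
       "T1ia", "T3ia", "T2ia", "T1ip", "T3ip", "T2ip", "T4"]
)

_GEOMETRIC_ZONES = _zones_from_labels(_GEOMETRIC_LABELS)
_REPORTABLE_ZONES = _zones_from_labels(_REPORTABLE_LABELS)


def enumerate_zones(
    variant: SchemeVariant | str = SchemeVariant.NATIVE,
    level: str = "geometric",
) -> tuple[ZoneID, ...]:
    """Enumerate the scheme's zones in canonical order.

    Parameters
    ----------
    variant
        ``native`` or ``postoperative``.  Both variants share the identical
        label set (they differ only in partition geometry), so the result is
        the same; the argument is validated for caller hygiene.
    level
        ``geometric`` returns the 30 voxel-level zones (9 femoral including
        the reference zone, 8 patellar, 13 tibial).  ``reportable`` returns
        the 25 uptake-report rows in report order: patellar depth sub-zones
        are collapsed (``P1s`` etc.) and the reference zone is omitted
        (it is reported separately as the normalization denominator).
    """
    _as_variant(variant)
    if level == "geometric":
        return _GEOMETRIC_ZONES
    if level == "reportable":
        return _REPORTABLE_ZONES
    raise InvalidZoneError(
        f"unknown zone level {level!r}; expected 'geometric' or 'reportable'"
    )


def reportable_members(zone: ZoneID) -> tuple[ZoneID, ...]:
    """Geometric zones aggregated into one reportable row.

    Patellar reportable rows collapse their anterior/posterior sub-zones (the
    row value is the maximum over both); every other reportable row is its
    own geometric zone.
    """
    if zone.bone == Bone.PATELLA and zone.depth is None:
        return (
            ZoneID(zone.bone, zone.column, zone.vertical, Depth.ANTERIOR),
            ZoneID(zone.bone, zone.column, zone.vertical, Depth.POSTERIOR),
        )
    return (zone,)
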