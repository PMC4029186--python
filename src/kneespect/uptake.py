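"""Per-zone maximum uptake extraction and reference normalization.

For every reportable zone the maximum voxel value (the volume-of-interest
statistic) is divided by the mean uptake of the femoral-shaft reference zone
``R``, yielding dimensionless ratios that are comparable across patients,
timepoints and acquisitions.  Patellar reportable rows take the maximum over
their two anterior/posterior geometric sub-zones before normalization.

Zones that fall outside the field of view yield flagged missing values
(``NaN`` with ``missing=True`` in the report table), never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import math

import numpy as np
import pandas as pd

from .errors import MissingReferenceError, ZeroReferenceError
from .partition import LandmarkSet, PartitionParams, ZoneLabelMap, partition_volume
from .scheme import (
    REFERENCE_ZONE,
    SchemeVariant,
    ZoneID,
    enumerate_zones,
    reportable_members,
    _as_variant,
)
from .volume import UptakeVolume

__all__ = [
    "UptakeVolume",
    "ZoneUptakeReport",
    "reference_value",
    "zone_max",
    "normalize",
    "build_report",
]

_REFERENCE_STATS = {
    "mean": np.mean,
    "median": np.median,
    "max": np.max,
}


def reference_value(
    volume: UptakeVolume, labelmap: ZoneLabelMap, stat: str = "mean"
) -> float:
    """Reference-region uptake used as the normalization denominator.

    By default the arithmetic mean over the femoral-shaft reference zone
    ``R`` (``stat`` may also be ``"median"`` or ``"max"``).

    Raises
    ------
    MissingReferenceError
        If the reference zone has no voxels in the label map.
    ZeroReferenceError
        If the reference statistic is not strictly positive.
    """
    if stat not in _REFERENCE_STATS:
        raise ZeroReferenceError(
            f"unknown reference statistic {stat!r}; expected one of "
            f"{sorted(_REFERENCE_STATS)}"
        )
    mask = labelmap.mask(REFERENCE_ZONE)
    if not np.any(mask):
        raise MissingReferenceError("reference zone R is empty in the label map")
    value = float(_REFERENCE_STATS[stat](volume.grid[mask]))
    if value <= 0:
        raise ZeroReferenceError(
            f"reference-region {stat} is {value:g}; normalization requires a "
            "strictly positive reference"
        )
    return value


def zone_max(
    volume: UptakeVolume, labelmap: ZoneLabelMap, zone: ZoneID | str
) -> float:
    """Maximum voxel value over a zone's voxel set.

    Returns ``NaN`` (the missing-value flag) for a zone that is present in
    the legend but has no voxels, e.g. due to field-of-view truncation.
    Raises :class:`~kneespect.errors.InvalidZoneError` for a zone unknown to
    the legend.
    """
    mask = labelmap.mask(zone)
    if not np.any(mask):
        return float("nan")
    return float(volume.grid[mask].max())


def normalize(raw_max: float, reference: float) -> float:
    """Dimensionless uptake ratio ``raw_max / reference``.

    A ``NaN`` numerator (missing zone) propagates; a non-positive reference
    raises :class:`~kneespect.errors.ZeroReferenceError`.
    """
    if not (reference > 0):
        raise ZeroReferenceError(f"reference value must be > 0, got {reference!r}")
    return float(raw_max) / float(reference)


@dataclass
class ZoneUptakeReport:
    """Per-knee uptake report: one row per reportable zone, in report order."""

    table: pd.DataFrame
    reference_value: float
    variant: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ratios = self.table["ratio"].to_numpy(dtype=float)
        finite = ratios[np.isfinite(ratios)]
        if np.any(finite < 0):
            raise ZeroReferenceError("uptake ratios must be non-negative")

    def to_json_dict(self) -> dict[str, Any]:
        rows = self.table.replace({np.nan: None}).to_dict(orient="records")
        return {
            "metadata": dict(self.metadata),
            "variant": self.variant,
            "reference_value": self.reference_value,
            "zones": rows,
        }


def build_report(
    volume: UptakeVolume,
    landmarks: LandmarkSet,
    variant: SchemeVariant | str = SchemeVariant.NATIVE,
    bone_masks: dict[str, np.ndarray] | None = None,
    params: PartitionParams | None = None,
    reference_stat: str = "mean",
    metadata: dict[str, Any] | None = None,
    labelmap: ZoneLabelMap | None = None,
) -> ZoneUptakeReport:
    """Partition the volume and assemble the normalized per-zone report.

    ``labelmap`` may be supplied to reuse an existing partition; otherwise
    :func:`~kneespect.partition.partition_volume` is run with the given
    landmarks/variant/params.
    """
    variant = _as_variant(variant)
    if labelmap is None:
        labelmap = partition_volume(volume, landmarks, variant, bone_masks, params)
    ref = reference_value(volume, labelmap, stat=reference_stat)

    rows = []
    for zone in enumerate_zones(variant, "reportable"):
        member_maxes = [zone_max(volume, labelmap, m) for m in reportable_members(zone)]
        finite = [m for m in member_maxes if not math.isnan(m)]
        raw = max(finite) if finite else float("nan")
        rows.append(
            {
                "zone": str(zone),
                "raw_max": raw,
                "ratio": normalize(raw, ref),
                "missing": not finite,
            }
        )
    table = pd.DataFrame(rows, columns=["zone", "raw_max", "ratio", "missing"])
    return ZoneUptakeReport(
        table=table,
        reference_value=ref,
        variant=variant.value,
        metadata=dict(metadata or {}),
    )
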