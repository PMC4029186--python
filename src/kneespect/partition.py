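"""Landmark-parametric partition of a knee volume into anatomical zones.

Every voxel of each bone's region of interest is assigned to exactly one
geometric zone of the localization scheme.  Zone boundaries are planes in an
anatomical *knee frame* derived from the alignment landmarks (femoral head
centre, epicondyles, tibial plateau centre, talar centre):

* a sagittal plane through the relevant bone centre splits medial (column 1)
  from lateral (column 2); for the tibia two parasagittal planes at +-1/6 of
  the plateau width delimit the intercondylar column 3 (the middle third);
* a transverse plane at a bone-specific level splits superior from inferior
  (femur: the epicondylar level; tibia: a configurable offset below the joint
  line; patella: the patella centre);
* a coronal plane through the bone centre splits anterior from posterior.

The tibia additionally carves the distal plate area ``T4`` (a padded box
around the osteosynthesis-plate landmarks in the postoperative variant, a
distal slab of the tibial ROI in the native variant), and the femur carves
the cylindrical shaft reference zone ``R`` used for uptake normalization.

Voxel membership is evaluated at the voxel centre in physical millimetre
coordinates, so the partition commutes with rigid motion of grid and
landmarks together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, GeometryError, InvalidZoneError, MissingLandmarkError
from .scheme import SchemeVariant, ZoneID, enumerate_zones, parse_zone_label, _as_variant
from .volume import UptakeVolume

__all__ = [
    "LandmarkSet",
    "KneeFrame",
    "PartitionParams",
    "ZoneLabelMap",
    "knee_frame",
    "partition_volume",
]

_BONES = ("femur", "tibia", "patella")

MANDATORY_LANDMARKS = (
    "femoral_head_center",
    "medial_epicondyle",
    "lateral_epicondyle",
    "tibial_plateau_center",
    "talar_center",
)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise GeometryError(f"degenerate geometry: {what} has (near-)zero length")
    return v / n


@dataclass
class LandmarkSet:
    """Named anatomical landmarks in physical RAS millimetre coordinates.

    The five mandatory points define the mechanical axes and the knee frame.
    Auxiliary entries are needed for volume partitioning only:
    ``femoral_shaft_point`` (reference-cylinder centre), ``patella_center``,
    ``joint_line_level`` (longitudinal knee-frame coordinate of the tibial
    joint line, mm), ``bone_extents`` (per-bone axis-aligned boxes in
    knee-frame (mediolateral, anterior, longitudinal) coordinates, used when
    no bone masks are supplied), and - postoperative only - ``plate_proximal``
    / ``plate_distal``.  ``tibial_tuberosity`` is accepted for completeness
    but not consumed by any partition rule.
    """

    femoral_head_center: np.ndarray
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    tibial_plateau_center: np.ndarray
    talar_center: np.ndarray
    side: str = "right"
    patella_center: np.ndarray | None = None
    tibial_tuberosity: np.ndarray | None = None
    femoral_shaft_point: np.ndarray | None = None
    joint_line_level: float | None = None
    bone_extents: dict[str, np.ndarray] | None = None
    plate_proximal: np.ndarray | None = None
    plate_distal: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in (
            "femoral_head_center",
            "medial_epicondyle",
            "lateral_epicondyle",
            "tibial_plateau_center",
            "talar_center",
            "patella_center",
            "tibial_tuberosity",
            "femoral_shaft_point",
            "plate_proximal",
            "plate_distal",
        ):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=np.float64).reshape(3))
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.linalg.norm(self.medial_epicondyle - self.lateral_epicondyle) < 1e-9:
            raise GeometryError("medial and lateral epicondyles coincide")
        longi = _unit(
            self.femoral_head_center - self.talar_center, "hip-to-ankle axis"
        )
        if np.dot(self.femoral_head_center - self.tibial_plateau_center, longi) <= 0:
            raise GeometryError(
                "femoral head centre is not superior to the tibial plateau centre"
            )
        if np.dot(self.tibial_plateau_center - self.talar_center, longi) <= 0:
            raise GeometryError(
                "tibial plateau centre is not superior to the talar centre"
            )
        if self.bone_extents is not None:
            self.bone_extents = {
                k: np.asarray(v, dtype=np.float64).reshape(2, 3)
                for k, v in self.bone_extents.items()
            }

    @property
    def epicondyle_midpoint(self) -> np.ndarray:
        return 0.5 * (self.medial_epicondyle + self.lateral_epicondyle)

    def check_side_consistency(self) -> None:
        """Verify the labelled medial epicondyle lies on the medial side.

        In patient RAS space the medial side of a *right* knee faces -x
        (towards the body midline) and of a *left* knee +x.  Only meaningful
        for volumes in patient orientation; callers working in arbitrary
        rotated frames should skip this check.
        """
        dx = float(self.medial_epicondyle[0] - self.lateral_epicondyle[0])
        if (self.side == "right" and dx >= 0) or (self.side == "left" and dx <= 0):
            raise GeometryError(
                f"labelled medial epicondyle is not on the medial side for a "
                f"{self.side} knee (medial-lateral x difference {dx:+.1f} mm)"
            )


@dataclass
class KneeFrame:
    """Orthonormal anatomical frame at the knee.

    ``si`` points from the talar centre towards the femoral head (superior),
    ``ml`` is the epicondylar direction orthogonalized against ``si``
    (medial -> lateral), and ``ap`` completes a right-handed frame.  The
    side-resolved ``anterior`` axis (``ap`` for right knees, ``-ap`` for
    left) is what partition depth tests use, so anterior/posterior labels are
    anatomically correct for both sides.
    """

    origin: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    si: np.ndarray
    side: str = "right"

    @property
    def anterior(self) -> np.ndarray:
        return self.ap if self.side == "right" else -self.ap

    def local(self, points: np.ndarray) -> np.ndarray:
        """(mediolateral, anterior, longitudinal) coordinates of points, mm."""
        rel = np.asarray(points, dtype=np.float64) - self.origin
        basis = np.stack([self.ml, self.anterior, self.si], axis=-1)
        return rel @ basis


def knee_frame(landmarks: LandmarkSet) -> KneeFrame:
    """Construct the anatomical knee frame from the mandatory landmarks."""
    si = _unit(
        landmarks.femoral_head_center - landmarks.talar_center, "hip-to-ankle axis"
    )
    ml_raw = landmarks.lateral_epicondyle - landmarks.medial_epicondyle
    ml = ml_raw - np.dot(ml_raw, si) * si
    if np.linalg.norm(ml) < 1e-9 * max(1.0, float(np.linalg.norm(ml_raw))):
        raise GeometryError(
            "epicondylar axis is parallel to the longitudinal axis "
            "(mediolateral direction undefined)"
        )
    ml = _unit(ml, "mediolateral axis")
    ap = np.cross(si, ml)
    return KneeFrame(
        origin=landmarks.tibial_plateau_center.copy(),
        ml=ml,
        ap=ap,
        si=si,
        side=landmarks.side,
    )


@dataclass
class PartitionParams:
    """Tunable geometry of the zone partition (all lengths in mm)."""

    tibial_si_offset_mm: float = 15.0   # transverse s/i plane below the joint line
    postop_si_shift_mm: float = 10.0    # extra inferior shift clearing the osteotomy gap
    t4_native_height_mm: float = 25.0   # distal tibial slab labelled T4 (native)
    t4_plate_pad_mm: float = 10.0       # padding of the plate box (postoperative)
    reference_radius_mm: float = 10.0   # femoral-shaft reference cylinder
    reference_height_mm: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "tibial_si_offset_mm",
            "t4_native_height_mm",
            "t4_plate_pad_mm",
            "reference_radius_mm",
            "reference_height_mm",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"partition parameter {name} must be > 0")
        if self.postop_si_shift_mm < 0:
            raise GeometryError("postop_si_shift_mm must be >= 0")


@dataclass
class ZoneLabelMap:
    """Integer zone-label volume congruent with its source uptake volume."""

    grid: np.ndarray
    legend: dict[int, ZoneID]
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def name_to_label(self) -> dict[str, int]:
        return {str(z): i for i, z in self.legend.items()}

    def label_of(self, zone: ZoneID | str) -> int:
        name = str(zone) if isinstance(zone, ZoneID) else str(parse_zone_label(zone))
        try:
            return self.name_to_label[name]
        except KeyError:
            raise InvalidZoneError(f"zone {name!r} is not in the label-map legend") from None

    def mask(self, zone: ZoneID | str) -> np.ndarray:
        return self.grid == self.label_of(zone)

    def voxel_counts(self) -> dict[str, int]:
        return {str(z): int(np.sum(self.grid == i)) for i, z in self.legend.items()}


def _check_in_bounds(volume: UptakeVolume, landmarks: LandmarkSet) -> None:
    lo, hi = volume.physical_bounds()
    names = list(MANDATORY_LANDMARKS) + [
        "patella_center",
        "femoral_shaft_point",
        "plate_proximal",
        "plate_distal",
    ]
    for name in names:
        p = getattr(landmarks, name, None)
        if p is None:
            continue
        if np.any(p < lo - 1e-6) or np.any(p > hi + 1e-6):
            raise BoundsError(
                f"landmark {name} at {np.round(p, 2).tolist()} lies outside the "
                f"volume bounds {np.round(lo, 2).tolist()}..{np.round(hi, 2).tolist()}"
            )


def _require(landmarks: LandmarkSet, name: str):
    v = getattr(landmarks, name)
    if v is None:
        raise MissingLandmarkError(f"required landmark/field {name!r} is missing")
    return v


def _box_mask(local: np.ndarray, box: np.ndarray) -> np.ndarray:
    lo, hi = box[0], box[1]
    return np.all((local >= lo) & (local <= hi), axis=-1)


def partition_volume(
    volume: UptakeVolume,
    landmarks: LandmarkSet,
    variant: SchemeVariant | str = SchemeVariant.NATIVE,
    bone_masks: dict[str, np.ndarray] | None = None,
    params: PartitionParams | None = None,
) -> ZoneLabelMap:
    """Assign every bone-ROI voxel to exactly one geometric zone.

    Parameters
    ----------
    volume
        The uptake volume whose grid geometry the label map inherits.
    landmarks
        Landmark set; partitioning requires the auxiliary fields (shaft
        point, patella centre, joint-line level, and either ``bone_masks``
        here or ``bone_extents`` on the landmark set; plate landmarks for the
        postoperative variant).
    variant
        ``native`` or ``postoperative``; both emit the identical label set,
        the postoperative variant places ``T4`` at the plate box and shifts
        the tibial superior/inferior plane inferiorly.
    bone_masks
        Optional ``{"femur"|"tibia"|"patella": bool array}`` regions of
        interest congruent with ``volume``; when omitted, axis-aligned boxes
        from ``landmarks.bone_extents`` (knee-frame coordinates) are used.

    Returns
    -------
    ZoneLabelMap
        Integer label grid (0 = background) plus a legend mapping label
        integers to :class:`~kneespect.scheme.ZoneID`.
    """
    variant = _as_variant(variant)
    params = params or PartitionParams()
    frame = knee_frame(landmarks)
    _check_in_bounds(volume, landmarks)

    centers = volume.voxel_centers()
    local = frame.local(centers)
    ml, ant, si = local[..., 0], local[..., 1], local[..., 2]

    # --- bone regions of interest -------------------------------------------------
    rois: dict[str, np.ndarray] = {}
    if bone_masks is not None:
        for bone, m in bone_masks.items():
            if bone not in _BONES:
                raise InvalidZoneError(f"unknown bone {bone!r} in bone_masks")
            m = np.asarray(m, dtype=bool)
            if m.shape != volume.grid.shape:
                raise GeometryError(
                    f"bone mask {bone!r} shape {m.shape} is not congruent with the "
                    f"volume shape {volume.grid.shape}"
                )
            rois[bone] = m
    else:
        extents = landmarks.bone_extents
        if extents is None:
            raise MissingLandmarkError(
                "required landmark/field 'bone_extents' is missing "
                "(or supply bone_masks)"
            )
        for bone in _BONES:
            if bone not in extents:
                raise MissingLandmarkError(
                    f"required landmark/field 'bone_extents[{bone!r}]' is missing"
                )
            rois[bone] = _box_mask(local, extents[bone])

    bones = list(rois)
    for i, a in enumerate(bones):
        for b in bones[i + 1 :]:
            if np.any(rois[a] & rois[b]):
                raise GeometryError(f"bone regions {a!r} and {b!r} overlap")

    zones = enumerate_zones(variant, "geometric")
    legend = {i + 1: z for i, z in enumerate(zones)}
    index = {str(z): i + 1 for i, z in enumerate(zones)}
    labels = np.zeros(volume.grid.shape, dtype=np.int16)

    def assign_quadrants(mask: np.ndarray, bone_letter: str, col: np.ndarray,
                         si_level: float, ant_level: float) -> None:
        vert = np.where(si > si_level, "s", "i")
        depth = np.where(ant > ant_level, "a", "p")
        cols = np.unique(col[mask]) if np.any(mask) else []
        for c in cols:
            for v in ("s", "i"):
                for d in ("a", "p"):
                    sel = mask & (col == c) & (vert == v) & (depth == d)
                    if np.any(sel):
                        labels[sel] = index[f"{bone_letter}{int(c)}{v}{d}"]

    # --- femur: reference cylinder R, then condylar quadrants ---------------------
    if "femur" in rois:
        roi = rois["femur"]
        shaft_point = _require(landmarks, "femoral_shaft_point")
        shaft_axis = _unit(
            landmarks.femoral_head_center - landmarks.tibial_plateau_center,
            "femoral shaft axis",
        )
        rel = centers - shaft_point
        along = rel @ shaft_axis
        rad2 = np.einsum("...a,...a->...", rel, rel) - along**2
        r_mask = (
            roi
            & (np.abs(along) <= params.reference_height_mm / 2.0)
            & (rad2 <= params.reference_radius_mm**2)
        )
        labels[r_mask] = index["R"]
        cml, cant, csi = frame.local(landmarks.epicondyle_midpoint)
        col = np.where(ml < cml, 1, 2)
        assign_quadrants(roi & ~r_mask, "F", col, csi, cant)

    # --- patella ------------------------------------------------------------------
    if "patella" in rois:
        roi = rois["patella"]
        if np.any(roi):
            pc = _require(landmarks, "patella_center")
            cml, cant, csi = frame.local(pc)
            col = np.where(ml < cml, 1, 2)
            assign_quadrants(roi, "P", col, csi, cant)

    # --- tibia: T4 carve-out, then columns 1/3/2 ----------------------------------
    if "tibia" in rois:
        roi = rois["tibia"]
        joint_line = _require(landmarks, "joint_line_level")
        if variant == SchemeVariant.POSTOPERATIVE:
            pp = frame.local(_require(landmarks, "plate_proximal"))
            pd_ = frame.local(_require(landmarks, "plate_distal"))
            lo = np.minimum(pp, pd_) - params.t4_plate_pad_mm
            hi = np.maximum(pp, pd_) + params.t4_plate_pad_mm
            t4 = roi & np.all((local >= lo) & (local <= hi), axis=-1)
        else:
            if landmarks.bone_extents is not None and "tibia" in landmarks.bone_extents:
                si_min = float(landmarks.bone_extents["tibia"][0, 2])
            elif np.any(roi):
                si_min = float(si[roi].min())
            else:
                si_min = 0.0
            t4 = roi & (si < si_min + params.t4_native_height_mm)
        labels[t4] = index["T4"]

        rest = roi & ~t4
        pml, pant, _ = frame.local(landmarks.tibial_plateau_center)
        if landmarks.bone_extents is not None and "tibia" in landmarks.bone_extents:
            width = float(
                landmarks.bone_extents["tibia"][1, 0]
                - landmarks.bone_extents["tibia"][0, 0]
            )
        elif np.any(roi):
            width = max(float(ml[roi].max() - ml[roi].min()), 1.0)
        else:
            width = 1.0
        half_mid = width / 6.0
        col = np.full(ml.shape, 3)
        col[ml < pml - half_mid] = 1
        col[ml > pml + half_mid] = 2
        si_plane = float(joint_line) - params.tibial_si_offset_mm
        if variant == SchemeVariant.POSTOPERATIVE:
            si_plane -= params.postop_si_shift_mm
        assign_quadrants(rest, "T", col, si_plane, pant)

    return ZoneLabelMap(
        grid=labels,
        legend=legend,
        spacing=volume.spacing.copy(),
        origin=volume.origin.copy(),
        direction=volume.direction.copy(),
    )
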