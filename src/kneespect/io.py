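"""File readers/writers, run configuration, and the end-to-end pipeline.

All geometry is held internally in RAS millimetres; coordinate-convention
conversion (currently LPS -> RAS) happens only at the landmark-file boundary.
Volumes travel as NIfTI (.nii/.nii.gz) via nibabel, landmarks as JSON,
reports as CSV (with a ``#``-prefixed header block) plus a JSON twin, and
run configuration as a YAML key-value file.  Every pipeline run emits a
provenance block (input checksums, config hash, package/library versions) so
reliability-study reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .alignment import AlignmentResult, hka_angle
from .errors import ConfigError, FormatError, MissingLandmarkError
from .partition import (
    LandmarkSet,
    MANDATORY_LANDMARKS,
    PartitionParams,
    ZoneLabelMap,
    partition_volume,
)
from .scheme import _as_variant
from .uptake import ZoneUptakeReport, build_report
from .volume import UptakeVolume

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "write_labelmap",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger("kneespect")

_CONVENTIONS = ("RAS", "LPS")

_POINT_FIELDS = MANDATORY_LANDMARKS + (
    "patella_center",
    "tibial_tuberosity",
    "femoral_shaft_point",
    "plate_proximal",
    "plate_distal",
)


@dataclass
class RunConfig:
    """Serializable pipeline configuration with validated defaults."""

    variant: str = "native"
    tibial_si_offset_mm: float = 15.0
    postop_si_shift_mm: float = 10.0
    t4_native_height_mm: float = 25.0
    t4_plate_pad_mm: float = 10.0
    reference_radius_mm: float = 10.0
    reference_height_mm: float = 20.0
    reference_stat: str = "mean"
    session_pairing: str = "session1"
    convention: str = "RAS"
    precision: int = 3

    def __post_init__(self) -> None:
        _as_variant(self.variant)
        if self.reference_stat not in ("mean", "median", "max"):
            raise ConfigError(f"unknown reference_stat {self.reference_stat!r}")
        if self.session_pairing not in ("session1", "mean"):
            raise ConfigError(f"unknown session_pairing {self.session_pairing!r}")
        if self.convention not in _CONVENTIONS:
            raise ConfigError(
                f"unknown coordinate convention {self.convention!r}; "
                f"expected one of {_CONVENTIONS}"
            )
        if self.precision < 0:
            raise ConfigError("precision must be >= 0")
        self.partition_params()  # validates the positive lengths

    def partition_params(self) -> PartitionParams:
        return PartitionParams(
            tibial_si_offset_mm=self.tibial_si_offset_mm,
            postop_si_shift_mm=self.postop_si_shift_mm,
            t4_native_height_mm=self.t4_native_height_mm,
            t4_plate_pad_mm=self.t4_plate_pad_mm,
            reference_radius_mm=self.reference_radius_mm,
            reference_height_mm=self.reference_height_mm,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------- volumes

def read_volume(path: str | Path) -> UptakeVolume:
    """Read a NIfTI uptake volume, validating finiteness and non-negativity."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float64)
        affine = np.asarray(img.affine, dtype=np.float64)
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    if grid.ndim != 3:
        raise FormatError(f"volume {path} is {grid.ndim}D; expected a 3D scalar field")
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"volume {path} has a degenerate affine (zero spacing)")
    direction = lin / spacing[np.newaxis, :]
    return UptakeVolume(
        grid=grid, spacing=spacing, origin=affine[:3, 3], direction=direction
    )


def write_volume(volume: UptakeVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.grid, volume.affine)
    nib.save(img, str(path))


def write_labelmap(labelmap: ZoneLabelMap, path: str | Path) -> None:
    """Write the integer label volume (.nii/.nii.gz) plus a JSON legend twin."""
    affine = np.eye(4)
    affine[:3, :3] = labelmap.direction * labelmap.spacing[np.newaxis, :]
    affine[:3, 3] = labelmap.origin
    nib.save(nib.Nifti1Image(labelmap.grid.astype(np.int16), affine), str(path))
    legend = {str(i): str(z) for i, z in labelmap.legend.items()}
    _legend_path(path).write_text(json.dumps({"background": 0, "labels": legend}, indent=2))


def _legend_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + "_legend.json")
    return p.with_suffix(".legend.json")


# ------------------------------------------------------------------------- landmarks

def read_landmarks(path: str | Path, check_side: bool = True) -> LandmarkSet:
    """Read a landmark JSON file and convert to internal RAS millimetres.

    Expected structure::

        {"convention": "RAS"|"LPS", "side": "left"|"right",
         "points": {"femoral_head_center": [x,y,z], ...},
         "joint_line_level": 0.0,            # optional, knee-frame mm
         "bone_extents": {"femur": [[...],[...]], ...}}   # optional

    Raises explicit errors naming any missing mandatory point.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read landmark file {path}: {exc}") from exc
    convention = raw.get("convention", "RAS")
    if convention not in _CONVENTIONS:
        raise FormatError(
            f"unknown coordinate convention {convention!r} in {path}; "
            f"expected one of {_CONVENTIONS}"
        )
    side = raw.get("side")
    if side not in ("left", "right"):
        raise FormatError(f"landmark file {path} must declare side: left|right")
    points = raw.get("points", {})
    for name in MANDATORY_LANDMARKS:
        if name not in points:
            raise MissingLandmarkError(
                f"landmark file {path} is missing required point {name!r}"
            )

    def convert(p) -> np.ndarray:
        v = np.asarray(p, dtype=np.float64).reshape(3)
        if convention == "LPS":  # LPS -> RAS: flip x and y
            v = v * np.array([-1.0, -1.0, 1.0])
        return v

    kwargs: dict[str, Any] = {
        name: convert(points[name]) for name in _POINT_FIELDS if name in points
    }
    if "joint_line_level" in raw and raw["joint_line_level"] is not None:
        kwargs["joint_line_level"] = float(raw["joint_line_level"])
    if raw.get("bone_extents"):
        kwargs["bone_extents"] = {
            bone: np.asarray(box, dtype=np.float64).reshape(2, 3)
            for bone, box in raw["bone_extents"].items()
        }
    landmarks = LandmarkSet(side=side, **kwargs)
    if check_side:
        landmarks.check_side_consistency()
    return landmarks


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as RAS-convention JSON (round-trips losslessly)."""
    points = {
        name: np.asarray(getattr(landmarks, name)).tolist()
        for name in _POINT_FIELDS
        if getattr(landmarks, name) is not None
    }
    doc: dict[str, Any] = {
        "convention": "RAS",
        "side": landmarks.side,
        "points": points,
    }
    if landmarks.joint_line_level is not None:
        doc["joint_line_level"] = landmarks.joint_line_level
    if landmarks.bone_extents is not None:
        doc["bone_extents"] = {k: v.tolist() for k, v in landmarks.bone_extents.items()}
    Path(path).write_text(json.dumps(doc, indent=2))


# --------------------------------------------------------------------------- reports

def write_report(report: ZoneUptakeReport, csv_path: str | Path,
                 precision: int | None = None) -> None:
    """Write the zone report as CSV with a ``#`` header block, plus JSON twin."""
    csv_path = Path(csv_path)
    header = [
        f"# kneespect {__version__}",
        f"# variant={report.variant}",
        f"# reference_value={report.reference_value!r}",
    ]
    for key, value in sorted(report.metadata.items()):
        header.append(f"# {key}={value}")
    table = report.table
    if precision is not None:
        table = table.copy()
        for col in ("raw_max", "ratio"):
            table[col] = table[col].round(precision)
    body = table.to_csv(index=False)
    csv_path.write_text("\n".join(header) + "\n" + body)
    csv_path.with_suffix(".json").write_text(
        json.dumps(report.to_json_dict(), indent=2)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -------------------------------------------------------------------------- pipeline

def run_pipeline(
    volume_path: str | Path,
    landmarks_path: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path = ".",
    subject: str = "",
    timepoint: str = "",
) -> dict[str, Any]:
    """Read inputs, partition, quantify, measure alignment, write everything.

    Writes ``report.csv``/``report.json``, ``alignment.json``,
    ``labelmap.nii.gz`` (+ legend), and ``provenance.json`` into ``out_dir``;
    returns ``{"report": ZoneUptakeReport, "alignment": AlignmentResult,
    "labelmap": ZoneLabelMap, "provenance": dict}``.
    """
    config = config or RunConfig()
    volume_path, landmarks_path = Path(volume_path), Path(landmarks_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("reading volume %s and landmarks %s", volume_path, landmarks_path)
    volume = read_volume(volume_path)
    landmarks = read_landmarks(landmarks_path)

    params = config.partition_params()
    labelmap = partition_volume(volume, landmarks, config.variant, params=params)
    logger.info(
        "partitioned %d voxels into %d non-empty zones",
        int(np.sum(labelmap.grid > 0)),
        sum(1 for c in labelmap.voxel_counts().values() if c > 0),
    )
    report = build_report(
        volume,
        landmarks,
        config.variant,
        params=params,
        reference_stat=config.reference_stat,
        metadata={"subject": subject, "timepoint": timepoint},
        labelmap=labelmap,
    )
    result: AlignmentResult = hka_angle(landmarks)
    logger.info("mechanical alignment: %s", result.formatted(config.precision))

    write_report(report, out_dir / "report.csv", precision=None)
    (out_dir / "alignment.json").write_text(
        json.dumps(
            {
                "angle_deg": result.angle_deg,
                "direction": result.direction,
                "signed_deg": result.signed_deg,
                "formatted": result.formatted(config.precision),
            },
            indent=2,
        )
    )
    write_labelmap(labelmap, out_dir / "labelmap.nii.gz")
    provenance = {
        "kneespect_version": __version__,
        "numpy_version": np.__version__,
        "nibabel_version": nib.__version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "inputs": {
            volume_path.name: _sha256(volume_path),
            landmarks_path.name: _sha256(landmarks_path),
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "report": report,
        "alignment": result,
        "labelmap": labelmap,
        "provenance": provenance,
    }
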