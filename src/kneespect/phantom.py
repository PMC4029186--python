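"""Synthetic knee uptake phantoms and simulated rater datasets.

The phantom is a deliberately simple geometric stand-in for a knee SPECT/CT
study: bones are axis-aligned boxes in the anatomical knee frame, the
femoral-shaft reference region is a cylinder, and focal uptake ("hot spots",
emulating compartment overloading) are spheres of constant amplitude placed
inside declared zones.  This is *not* an anatomically realistic digital
phantom - it is controllable geometry with exact, analytically known ground
truth, so every partition/uptake/alignment rule can be verified end to end.

All randomness (Poisson counting noise, observer noise) flows through one
explicit integer seed per artifact; the same seed reproduces bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .partition import LandmarkSet, PartitionParams, partition_volume
from .scheme import (
    REFERENCE_ZONE,
    SchemeVariant,
    enumerate_zones,
    parse_zone_label,
    reportable_members,
    _as_variant,
)
from .volume import UptakeVolume

__all__ = [
    "HotSpot",
    "PhantomConfig",
    "RaterNoiseModel",
    "default_landmarks",
    "make_phantom",
    "simulate_raters",
]


@dataclass(frozen=True)
class HotSpot:
    """A spherical focal-uptake lesion inside one declared geometric zone.

    ``center`` (physical mm) may be omitted; the sphere is then auto-placed
    at the most interior point of the declared zone (the zone voxel with the
    largest distance to the zone boundary).
    """

    zone: str
    amplitude: float
    radius_mm: float = 5.0
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        parse_zone_label(self.zone)  # validates the label
        if self.amplitude < 0:
            raise ConfigError(f"hot-spot amplitude must be >= 0, got {self.amplitude}")
        if self.radius_mm <= 0:
            raise ConfigError(f"hot-spot radius must be > 0, got {self.radius_mm}")


@dataclass
class PhantomConfig:
    """Geometry, loading pattern, and noise of one synthetic knee volume."""

    shape: tuple[int, int, int] = (48, 48, 100)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    side: str = "right"
    variant: str = "native"
    baseline: float = 50.0          # background bone uptake (counts)
    reference_level: float = 50.0   # uptake filled into the reference cylinder
    hotspots: tuple[HotSpot, ...] = ()
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.hotspots = tuple(self.hotspots)
        _as_variant(self.variant)
        if self.baseline < 0 or self.reference_level <= 0:
            raise ConfigError(
                "baseline must be >= 0 and reference_level > 0, got "
                f"baseline={self.baseline}, reference_level={self.reference_level}"
            )
        half = (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0
        if half[0] < 40 or half[1] < 40 or half[2] < 120:
            raise ConfigError(
                "phantom grid is too small for the knee geometry: physical "
                f"half-extents {np.round(half, 1).tolist()} mm must reach at "
                "least (40, 40, 120) mm"
            )


def default_landmarks(
    shape: Sequence[int] = (48, 48, 100),
    spacing: Sequence[float] = (2.0, 2.0, 3.0),
    side: str = "right",
    variant: SchemeVariant | str = SchemeVariant.NATIVE,
    hka_deg: float = 0.0,
) -> LandmarkSet:
    """Landmark set of the canonical box-bone phantom, scaled to the grid.

    ``hka_deg`` tilts the tibial mechanical axis in the coronal plane
    (positive = varus), keeping all other geometry fixed, so phantoms with a
    known mechanical alignment can be generated.
    """
    variant = _as_variant(variant)
    half = (np.asarray(shape, float) - 1) * np.asarray(spacing, float) / 2.0
    x_half, y_half, z_half = half
    s = -1.0 if side == "right" else 1.0  # world-x sign of the medial direction

    plateau = np.array([0.0, 0.0, -4.0])
    hip = np.array([0.0, 0.0, 0.94 * z_half])
    ankle_drop = 0.88 * z_half - 4.0
    # Varus tilts the tibial axis medially going distal: the talar centre
    # shifts towards the medial side.
    talar = plateau + np.array(
        [s * ankle_drop * np.tan(np.radians(hka_deg)), 0.0, -ankle_drop]
    )
    medial_epi = np.array([s * 0.80 * x_half, 0.0, 10.0])
    lateral_epi = np.array([-s * 0.80 * x_half, 0.0, 10.0])

    extents = {
        # (mediolateral, anterior, longitudinal) knee-frame coordinates, mm
        "femur": np.array([[-0.90 * x_half, -0.90 * y_half, 4.0],
                           [0.90 * x_half, 0.55 * y_half, 0.99 * z_half]]),
        "tibia": np.array([[-0.85 * x_half, -0.90 * y_half, -0.93 * z_half],
                           [0.85 * x_half, 0.55 * y_half, 2.0]]),
        "patella": np.array([[-0.50 * x_half, 0.60 * y_half, -16.0],
                             [0.50 * x_half, 0.95 * y_half, 26.0]]),
    }
    plate_prox = plate_dist = None
    if variant == SchemeVariant.POSTOPERATIVE:
        plate_prox = plateau + np.array([s * 0.45 * x_half, 0.0, -16.0])
        plate_dist = plateau + np.array([s * 0.45 * x_half, 0.0, -56.0])

    return LandmarkSet(
        femoral_head_center=hip,
        medial_epicondyle=medial_epi,
        lateral_epicondyle=lateral_epi,
        tibial_plateau_center=plateau,
        talar_center=talar,
        side=side,
        patella_center=np.array([0.0, 0.76 * y_half, 1.0]),
        tibial_tuberosity=np.array([0.0, 0.50 * y_half, -30.0]),
        femoral_shaft_point=np.array([0.0, 0.0, 0.70 * z_half]),
        joint_line_level=0.0,
        bone_extents=extents,
        plate_proximal=plate_prox,
        plate_distal=plate_dist,
    )


def _interior_point(mask: np.ndarray, volume: UptakeVolume) -> np.ndarray:
    """Physical coordinates of the most interior voxel of a zone mask."""
    dist = ndimage.distance_transform_edt(mask, sampling=volume.spacing)
    idx = np.unravel_index(int(np.argmax(dist)), mask.shape)
    return volume.origin + volume.affine[:3, :3] @ np.asarray(idx, dtype=float)


def _truth_table(config: PhantomConfig) -> pd.DataFrame:
    hot_by_zone = {h.zone: h for h in config.hotspots}
    rows = []
    for zone in enumerate_zones(config.variant, "reportable"):
        amp = 0.0
        for member in reportable_members(zone):
            h = hot_by_zone.get(str(member)) or hot_by_zone.get(str(zone))
            if h is not None:
                amp = max(amp, h.amplitude)
        true_max = config.baseline + amp
        rows.append(
            {
                "zone": str(zone),
                "true_max": true_max,
                "true_ratio": true_max / config.reference_level,
            }
        )
    return pd.DataFrame(rows, columns=["zone", "true_max", "true_ratio"])


def make_phantom(
    config: PhantomConfig, params: PartitionParams | None = None
) -> tuple[UptakeVolume, LandmarkSet, pd.DataFrame]:
    """Generate a synthetic uptake volume, its landmarks, and ground truth.

    The returned table lists, for every reportable zone, the intended
    pre-noise maximum uptake and its normalized ratio
    ``(baseline + amplitude) / reference_level``; zones without a hot spot
    have ratio ``baseline / reference_level``.  Each hot sphere is validated
    to lie entirely inside its declared zone (and outside the reference
    region), so the noise-free phantom reproduces the table exactly through
    partition + uptake.

    Deterministic given ``config.seed`` (relevant only with Poisson noise).
    """
    params = params or PartitionParams()
    shape = tuple(config.shape)
    spacing = np.asarray(config.spacing, dtype=float)
    origin = -(np.asarray(shape, float) - 1) * spacing / 2.0
    grid = np.full(shape, float(config.baseline))
    vol = UptakeVolume(grid=grid, spacing=spacing, origin=origin)

    landmarks = default_landmarks(shape, spacing, config.side, config.variant)
    labelmap = partition_volume(vol, landmarks, config.variant, params=params)

    ref_mask = labelmap.mask(REFERENCE_ZONE)
    vol.grid[ref_mask] = float(config.reference_level)

    centers = vol.voxel_centers()
    seen: set[str] = set()
    for hot in config.hotspots:
        if hot.zone in seen:
            raise ConfigError(f"duplicate hot spot for zone {hot.zone!r}")
        seen.add(hot.zone)
        zone_mask = labelmap.mask(hot.zone)
        if not np.any(zone_mask):
            raise ConfigError(f"declared hot-spot zone {hot.zone!r} has no voxels")
        center = (
            np.asarray(hot.center, dtype=float)
            if hot.center is not None
            else _interior_point(zone_mask, vol)
        )
        sphere = (
            np.einsum("...a,...a->...", centers - center, centers - center)
            <= hot.radius_mm**2
        )
        if not np.any(sphere):
            raise ConfigError(
                f"hot spot in {hot.zone!r} covers no voxel centres "
                f"(radius {hot.radius_mm} mm too small for the grid)"
            )
        outside = sphere & ~zone_mask
        if np.any(outside):
            raise ConfigError(
                f"hot spot declared in zone {hot.zone!r} spills outside it "
                f"({int(outside.sum())} voxel(s)); shrink the radius or move the centre"
            )
        vol.grid[sphere] = config.baseline + hot.amplitude

    if config.poisson_noise:
        rng = np.random.default_rng(config.seed)
        vol.grid = rng.poisson(vol.grid).astype(np.float64)

    return vol, landmarks, _truth_table(config)


@dataclass(frozen=True)
class RaterNoiseModel:
    """Observer reading-error model for simulated reliability studies.

    Either a continuous zero-mean Gaussian error (``sd``) or a discrete
    reading-error distribution (``discrete_values`` with
    ``discrete_probs``, e.g. -1/0/+1 degree rounding errors for alignment
    readings).  ``biases`` adds a fixed per-observer offset.
    """

    sd: float = 0.0
    discrete_values: tuple[float, ...] | None = None
    discrete_probs: tuple[float, ...] | None = None
    biases: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"noise SD must be >= 0, got {self.sd}")
        if (self.discrete_values is None) != (self.discrete_probs is None):
            raise ConfigError("discrete_values and discrete_probs must be given together")
        if self.discrete_probs is not None:
            p = np.asarray(self.discrete_probs, dtype=float)
            if len(p) != len(self.discrete_values):
                raise ConfigError("discrete_values and discrete_probs differ in length")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ConfigError(f"discrete probabilities must be >= 0 and sum to 1, got {p}")


def simulate_raters(
    truth: pd.DataFrame | pd.Series | np.ndarray,
    model: RaterNoiseModel,
    n_observers: int = 2,
    n_sessions: int = 2,
) -> pd.DataFrame:
    """Simulate a multi-observer, multi-session reading of known true values.

    ``truth`` is either a long table with columns ``subject, target, value``
    or a 1D sequence of per-subject values (target then defaults to
    ``"alignment"``).  Each recorded value is
    ``truth + observer_bias + independent error draw``; the output is the
    long-format rater dataset consumed by
    :func:`~kneespect.reliability.reliability_report`.
    """
    if n_observers < 1 or n_sessions < 1:
        raise ConfigError("n_observers and n_sessions must be >= 1")
    if isinstance(truth, pd.DataFrame):
        need = {"subject", "target", "value"}
        if not need.issubset(truth.columns):
            raise ConfigError(f"truth table needs columns {sorted(need)}")
        base = truth[["subject", "target", "value"]].copy()
    else:
        values = np.asarray(truth, dtype=float).ravel()
        base = pd.DataFrame(
            {
                "subject": [f"S{i + 1:03d}" for i in range(len(values))],
                "target": "alignment",
                "value": values,
            }
        )
    biases = list(model.biases) + [0.0] * max(0, n_observers - len(model.biases))

    rng = np.random.default_rng(model.seed)
    records = []
    for obs in range(1, n_observers + 1):
        for ses in range(1, n_sessions + 1):
            if model.discrete_values is not None:
                err = rng.choice(
                    np.asarray(model.discrete_values, dtype=float),
                    size=len(base),
                    p=np.asarray(model.discrete_probs, dtype=float),
                )
            elif model.sd > 0:
                err = rng.normal(0.0, model.sd, size=len(base))
            else:
                err = np.zeros(len(base))
            records.append(
                pd.DataFrame(
                    {
                        "subject": base["subject"],
                        "target": base["target"],
                        "observer": obs,
                        "session": ses,
                        "value": base["value"].to_numpy() + biases[obs - 1] + err,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
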