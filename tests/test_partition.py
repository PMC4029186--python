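"""Knee-frame construction and voxel zone assignment geometry."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kneespect import (
    LandmarkSet,
    PhantomConfig,
    UptakeVolume,
    default_landmarks,
    knee_frame,
    make_phantom,
    partition_volume,
)
from kneespect.errors import BoundsError, GeometryError, MissingLandmarkError

# Canonical phantom grid geometry (see kneespect.phantom.default_landmarks).
SHAPE = (48, 48, 100)
SPACING = np.array([2.0, 2.0, 3.0])
ORIGIN = -(np.asarray(SHAPE) - 1) * SPACING / 2.0
X_HALF = Y_HALF = 47.0
Z_HALF = 148.5


def simple_landmarks(**overrides):
    base = dict(
        femoral_head_center=(0, 0, 400),
        medial_epicondyle=(-40, 0, 10),
        lateral_epicondyle=(40, 0, 10),
        tibial_plateau_center=(0, 0, 0),
        talar_center=(0, 0, -350),
        side="right",
    )
    base.update(overrides)
    return LandmarkSet(**base)


class TestKneeFrame:
    def test_axis_aligned_landmarks_give_world_axes(self):
        frame = knee_frame(simple_landmarks())
        np.testing.assert_allclose(frame.si, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(frame.ml, [1, 0, 0], atol=1e-12)  # medial -> lateral
        np.testing.assert_allclose(frame.ap, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.anterior, [0, 1, 0], atol=1e-12)

    def test_frame_is_orthonormal_and_right_handed(self):
        lms = simple_landmarks(
            medial_epicondyle=(-38, 6, 14), lateral_epicondyle=(41, -3, 7)
        )
        frame = knee_frame(lms)
        basis = np.stack([frame.ml, frame.ap, frame.si])
        np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(np.cross(frame.ml, frame.ap), frame.si, atol=1e-9)

    def test_frame_rotates_with_the_landmarks(self):
        lms = simple_landmarks(
            medial_epicondyle=(-38, 6, 14), lateral_epicondyle=(41, -3, 7)
        )
        rot = Rotation.random(random_state=3).as_matrix()
        rotated = simple_landmarks(
            **{
                name: rot @ np.asarray(getattr(lms, name), float)
                for name in (
                    "femoral_head_center",
                    "medial_epicondyle",
                    "lateral_epicondyle",
                    "tibial_plateau_center",
                    "talar_center",
                )
            }
        )
        f0, f1 = knee_frame(lms), knee_frame(rotated)
        for axis in ("ml", "ap", "si"):
            np.testing.assert_allclose(
                getattr(f1, axis), rot @ getattr(f0, axis), atol=1e-9
            )

    def test_coincident_epicondyles_rejected(self):
        with pytest.raises(GeometryError):
            simple_landmarks(medial_epicondyle=(5, 0, 10), lateral_epicondyle=(5, 0, 10))

    def test_epicondylar_axis_parallel_to_longitudinal_rejected(self):
        lms = simple_landmarks(
            medial_epicondyle=(0, 0, 30), lateral_epicondyle=(0, 0, -10)
        )
        with pytest.raises(GeometryError):
            knee_frame(lms)

    def test_longitudinal_landmark_ordering_enforced(self):
        with pytest.raises(GeometryError):
            simple_landmarks(femoral_head_center=(0, 0, -400))


def local_coords(p):
    """Knee-frame coordinates of a world point for the default right phantom."""
    plateau = np.array([0.0, 0.0, -4.0])
    return np.asarray(p, float) - plateau  # ml=+x, anterior=+y, si=z+4


def expected_label(p):
    """Independent point-in-region oracle: explicit plane/box tests."""
    ml, ant, si = local_coords(p)
    boxes = {
        "femur": ((-0.9 * X_HALF, -0.9 * Y_HALF, 4.0),
                  (0.9 * X_HALF, 0.55 * Y_HALF, 0.99 * Z_HALF)),
        "tibia": ((-0.85 * X_HALF, -0.9 * Y_HALF, -0.93 * Z_HALF),
                  (0.85 * X_HALF, 0.55 * Y_HALF, 2.0)),
        "patella": ((-0.5 * X_HALF, 0.6 * Y_HALF, -16.0),
                    (0.5 * X_HALF, 0.95 * Y_HALF, 26.0)),
    }

    def inside(bone):
        lo, hi = boxes[bone]
        return all(lo[i] <= (ml, ant, si)[i] <= hi[i] for i in range(3))

    if inside("femur"):
        shaft_si = 0.70 * Z_HALF + 4.0
        if ml**2 + ant**2 <= 10.0**2 and abs(si - shaft_si) <= 10.0:
            return "R"
        col = 1 if ml < 0 else 2
        vert = "s" if si > 14.0 else "i"  # epicondylar level: z=10 -> si=14
        depth = "a" if ant > 0 else "p"
        return f"F{col}{vert}{depth}"
    if inside("patella"):
        col = 1 if ml < 0 else 2
        vert = "s" if si > 5.0 else "i"
        depth = "a" if ant > 0.76 * Y_HALF else "p"
        return f"P{col}{vert}{depth}"
    if inside("tibia"):
        if si < -0.93 * Z_HALF + 25.0:
            return "T4"
        width = 2 * 0.85 * X_HALF
        col = 1 if ml < -width / 6 else (2 if ml > width / 6 else 3)
        vert = "s" if si > -15.0 else "i"
        depth = "a" if ant > 0 else "p"
        return f"T{col}{vert}{depth}"
    return None


PROBES = [
    ((-21.0, 11.0, 31.5), "F1sa"),
    ((21.0, 11.0, 31.5), "F2sa"),
    ((-21.0, -11.0, 31.5), "F1sp"),
    ((-21.0, 11.0, 7.5), "F1ia"),
    ((1.0, 1.0, 103.5), "R"),
    ((-5.0, 37.0, 7.5), "P1sa"),
    ((5.0, 35.0, -2.5), "P2ip"),
    ((-21.0, 1.0, -40.5), "T1ia"),
    ((-1.0, -1.0, -10.5), "T3sp"),
    ((21.0, 1.0, -40.5), "T2ia"),
    ((-1.0, 1.0, -124.5), "T4"),
]


class TestPartition:
    @pytest.mark.parametrize("point,expected", PROBES)
    def test_probe_voxels_match_plane_test_oracle(self, uniform_labelmap, point, expected):
        assert expected_label(point) == expected  # oracle sanity
        idx = tuple(np.round((np.asarray(point) - ORIGIN) / SPACING).astype(int))
        label = int(uniform_labelmap.grid[idx])
        assert str(uniform_labelmap.legend[label]) == expected

    def test_partition_is_exhaustive_per_bone(self, uniform_phantom, uniform_labelmap):
        vol, lms, _ = uniform_phantom
        frame = knee_frame(lms)
        local = frame.local(vol.voxel_centers())
        for bone, letter in (("femur", "F"), ("tibia", "T"), ("patella", "P")):
            lo, hi = lms.bone_extents[bone]
            roi = np.all((local >= lo) & (local <= hi), axis=-1)
            zone_labels = [
                i for i, z in uniform_labelmap.legend.items()
                if str(z).startswith(letter) or (letter == "F" and str(z) == "R")
            ]
            in_zones = np.isin(uniform_labelmap.grid, zone_labels)
            assert np.array_equal(in_zones, roi)

    def test_zone_voxel_counts_conserve_roi_totals(self, uniform_labelmap):
        counts = uniform_labelmap.voxel_counts()
        assert sum(counts.values()) == int(np.sum(uniform_labelmap.grid > 0))
        assert all(c > 0 for c in counts.values())  # every zone in the field of view

    def test_bone_masks_reproduce_extent_partition(self, uniform_phantom, uniform_labelmap):
        vol, lms, _ = uniform_phantom
        frame = knee_frame(lms)
        local = frame.local(vol.voxel_centers())
        masks = {}
        for bone in ("femur", "tibia", "patella"):
            lo, hi = lms.bone_extents[bone]
            masks[bone] = np.all((local >= lo) & (local <= hi), axis=-1)
        from_masks = partition_volume(vol, lms, "native", bone_masks=masks)
        np.testing.assert_array_equal(from_masks.grid, uniform_labelmap.grid)

    def test_overlapping_bone_masks_rejected(self, uniform_phantom):
        vol, lms, _ = uniform_phantom
        full = np.ones(vol.grid.shape, dtype=bool)
        with pytest.raises(GeometryError, match="overlap"):
            partition_volume(vol, lms, bone_masks={"femur": full, "tibia": full})

    def test_incongruent_bone_mask_rejected(self, uniform_phantom):
        vol, lms, _ = uniform_phantom
        with pytest.raises(GeometryError, match="congruent"):
            partition_volume(vol, lms, bone_masks={"femur": np.ones((3, 3, 3), bool)})

    def test_postoperative_plate_box_labelled_t4(self, postop_phantom):
        vol, lms, _ = postop_phantom
        postop = partition_volume(vol, lms, "postoperative")
        native_lms = default_landmarks(variant="native")
        native = partition_volume(vol, native_lms, "native")
        # plate midpoint: medial tibia, between the plate landmarks
        mid = 0.5 * (lms.plate_proximal + lms.plate_distal)
        idx = tuple(np.round((mid - ORIGIN) / SPACING).astype(int))
        assert str(postop.legend[int(postop.grid[idx])]) == "T4"
        # the same spot is an ordinary medial tibial zone in the native scheme
        assert str(native.legend[int(native.grid[idx])]).startswith("T1")

    def test_mirrored_knee_swaps_medial_and_lateral_labels(self, uniform_phantom, uniform_labelmap):
        vol, lms, _ = uniform_phantom
        mirror = np.array([-1.0, 1.0, 1.0])
        mirrored = dataclasses.replace(
            lms,
            femoral_head_center=lms.femoral_head_center * mirror,
            medial_epicondyle=lms.medial_epicondyle * mirror,
            lateral_epicondyle=lms.lateral_epicondyle * mirror,
            tibial_plateau_center=lms.tibial_plateau_center * mirror,
            talar_center=lms.talar_center * mirror,
            patella_center=lms.patella_center * mirror,
            femoral_shaft_point=lms.femoral_shaft_point * mirror,
            side="left",
        )
        flipped = partition_volume(vol, mirrored, "native")
        swap = {}
        for i, z in uniform_labelmap.legend.items():
            name = str(z)
            swapped = name.translate(str.maketrans("12", "21")) if name != "R" else "R"
            swap[i] = flipped.name_to_label[swapped]
        expected = np.zeros_like(uniform_labelmap.grid)
        for i, j in swap.items():
            expected[uniform_labelmap.grid == i] = j
        np.testing.assert_array_equal(flipped.grid, expected)

    def test_partition_commutes_with_rigid_rotation(self, uniform_phantom, uniform_labelmap):
        vol, lms, _ = uniform_phantom
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        vol2 = UptakeVolume(
            grid=vol.grid, spacing=vol.spacing, origin=rot @ vol.origin, direction=rot
        )
        point_fields = (
            "femoral_head_center", "medial_epicondyle", "lateral_epicondyle",
            "tibial_plateau_center", "talar_center", "patella_center",
            "femoral_shaft_point",
        )
        lms2 = dataclasses.replace(
            lms, **{f: rot @ getattr(lms, f) for f in point_fields}
        )
        rotated = partition_volume(vol2, lms2, "native")
        np.testing.assert_array_equal(rotated.grid, uniform_labelmap.grid)

    def test_missing_auxiliary_landmarks_named_in_error(self, uniform_phantom):
        vol, lms, _ = uniform_phantom
        no_shaft = dataclasses.replace(lms, femoral_shaft_point=None)
        with pytest.raises(MissingLandmarkError, match="femoral_shaft_point"):
            partition_volume(vol, no_shaft, "native")
        no_extents = dataclasses.replace(lms, bone_extents=None)
        with pytest.raises(MissingLandmarkError, match="bone_extents"):
            partition_volume(vol, no_extents, "native")
        no_joint = dataclasses.replace(lms, joint_line_level=None)
        with pytest.raises(MissingLandmarkError, match="joint_line_level"):
            partition_volume(vol, no_joint, "native")

    def test_postoperative_requires_plate_landmarks(self, uniform_phantom):
        vol, lms, _ = uniform_phantom  # native landmarks: no plate points
        with pytest.raises(MissingLandmarkError, match="plate_proximal"):
            partition_volume(vol, lms, "postoperative")

    def test_landmark_outside_volume_rejected(self, uniform_phantom):
        vol, lms, _ = uniform_phantom
        outside = dataclasses.replace(lms, femoral_head_center=(0.0, 0.0, 1000.0))
        with pytest.raises(BoundsError, match="femoral_head_center"):
            partition_volume(vol, outside, "native")
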