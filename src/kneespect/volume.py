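"""In-memory container for a 3D scalar uptake volume with physical geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["UptakeVolume"]


@dataclass
class UptakeVolume:
    """A 3D non-negative scalar field (tracer counts or arbitrary units).

    Geometry follows the usual medical-imaging convention: voxel centre at
    index ``(i, j, k)`` sits at physical position
    ``origin + direction @ (spacing * (i, j, k))`` in RAS millimetres.
    ``direction`` is an orthonormal 3x3 matrix (identity for an axis-aligned
    grid; axis permutations/flips and rigid rotations are supported).
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if self.grid.ndim != 3:
            raise FormatError(f"uptake grid must be 3D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            n = int(np.sum(~np.isfinite(self.grid)))
            raise FormatError(f"uptake grid contains {n} non-finite voxel(s)")
        if np.any(self.grid < 0):
            raise FormatError(
                f"uptake grid contains negative voxels (min {self.grid.min():g})"
            )
        if np.any(self.spacing <= 0) or not np.all(np.isfinite(self.spacing)):
            raise FormatError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 index-to-physical affine (RAS mm)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of all voxel centres, shape ``grid.shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.grid.shape), indexing="ij"),
            axis=-1,
        ).astype(np.float64)
        return self.origin + np.einsum("ab,...b->...a", self.affine[:3, :3], idx)

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned physical bounding box of the voxel-centre lattice."""
        shape = np.asarray(self.grid.shape, dtype=np.float64) - 1.0
        corners = np.array(
            [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])]
        )
        phys = self.origin + corners @ (self.direction * self.spacing[np.newaxis, :]).T
        return phys.min(axis=0), phys.max(axis=0)

    def congruent_with(self, other: "UptakeVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )
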