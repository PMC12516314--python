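"""Template-space voxel lattice with world<->index mapping.

All world coordinates are millimetres in a RAS+ template space (x increases
to the right, so the left hemisphere has x < 0 and the mid-sagittal plane is
x = 0). The grid is axis-aligned: the affine is diagonal scaling plus a
translation, which is all the analysis needs and keeps the world<->index
mapping exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in template millimetre space.

    Parameters
    ----------
    shape:
        Number of voxels along x, y, z.
    spacing:
        Voxel edge lengths in mm.
    origin:
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # ------------------------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (RAS+, diagonal)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine, atol: float = 1e-6) -> "VoxelGrid":
        """Build a grid from a NIfTI-style affine; obliquity is rejected."""
        affine = np.asarray(affine, dtype=float)
        lin = affine[:3, :3]
        off_diag = lin - np.diag(np.diag(lin))
        if np.any(np.abs(off_diag) > atol):
            raise ValueError(
                "oblique affine not supported: resample the volume to an "
                f"axis-aligned RAS+ grid first (off-diagonal max {np.abs(off_diag).max():.3g})"
            )
        diag = np.diag(lin)
        if np.any(diag <= 0):
            raise ValueError(
                "affine must be RAS+ with positive voxel sizes; "
                "reorient the volume (e.g. nibabel.as_closest_canonical) first"
            )
        return cls(tuple(int(s) for s in shape[:3]), tuple(diag), tuple(affine[:3, 3]))

    # ------------------------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        """Length of a voxel's space diagonal in mm."""
        return float(np.linalg.norm(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        """Voxel index (int triplet or (n, 3) array) -> world mm of voxel centre."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, xyz) -> np.ndarray:
        """World mm -> fractional voxel index (round for the nearest voxel)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_index(self, xyz) -> np.ndarray:
        return np.rint(self.world_to_index(xyz)).astype(int)

    def contains_world(self, xyz) -> bool:
        """True if the point falls inside the grid's bounding box of voxel centres."""
        frac = self.world_to_index(xyz)
        shape = np.asarray(self.shape)
        return bool(np.all(frac >= -0.5) and np.all(frac <= shape - 0.5))

    def contains_index(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=int))
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of every voxel centre, as three broadcastable axes."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    # ------------------------------------------------------------------
    def is_symmetric_about_midsagittal(self, atol: float = 1e-9) -> bool:
        """True if the voxel-centre x coordinates are mirror-symmetric about x = 0."""
        x0 = self.origin[0]
        x_last = x0 + (self.shape[0] - 1) * self.spacing[0]
        return abs(x0 + x_last) <= atol

    def distance_to_point(self, centre) -> np.ndarray:
        """Euclidean mm distance of every voxel centre to ``centre``; full-shape array."""
        cx, cy, cz = np.asarray(centre, dtype=float)
        gx, gy, gz = self.coordinate_arrays()
        return np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2)
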