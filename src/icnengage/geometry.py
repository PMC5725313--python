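"""Voxel grid geometry shared by atlases and statistical maps.

A grid is a 3-D array shape plus a 4x4 voxel-to-world affine (mm, typically
MNI space). Two volumes are comparable only when their geometries match, so
everything downstream carries a :class:`GridGeometry` and checks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "GeometryError"]


class GeometryError(ValueError):
    """Raised when volume geometries are invalid or incompatible."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape and affine of a 3-D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, length 3.
    affine : (4, 4) ndarray
        Voxel-index to world-coordinate (mm) transform. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "GridGeometry", atol: float = 1e-6) -> bool:
        """Same shape and affine (within ``atol``)."""
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def check_volume(self, vol: np.ndarray, name: str = "volume") -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape != self.shape:
            raise GeometryError(
                f"{name} shape {vol.shape} does not match grid shape {self.shape}"
            )
        return vol
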