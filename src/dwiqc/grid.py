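"""Voxel-grid geometry shared by every image container in dwiqc.

Conventions
-----------
* World coordinates are millimetres with the scanner isocentre at ``(0, 0, 0)``.
* Axes: ``x`` runs right-left, ``y`` vertically (positive towards the bottom of
  the image, the direction in which table-height gradient nonlinearity shows up),
  ``z`` along the slice direction.
* The centre of voxel ``(i, j, k)`` sits at ``origin + (index + 0.5) * spacing``
  on each axis, i.e. ``origin`` is the low corner of the volume, not a voxel
  centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .exceptions import ValidationError

Triple = Tuple[float, float, float]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class GridSpec:
    """A regular 3-D voxel grid in scanner (isocentre-origin) coordinates."""

    shape: Tuple[int, int, int]
    spacing: Triple
    origin: Triple

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("GridSpec requires 3-component shape/spacing/origin")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise ValidationError(f"grid shape must be positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, shape: Tuple[int, int, int], spacing: Triple) -> "GridSpec":
        """Grid whose geometric centre is the isocentre.

        With an odd number of voxels along an axis the isocentre falls on a
        voxel centre, which makes centred ROIs and whole-voxel shifts exact.
        """
        origin = tuple(-n * s / 2.0 for n, s in zip(shape, spacing))
        return cls(tuple(shape), tuple(spacing), origin)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates (mm) along one axis (0=x, 1=y, 2=z)."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse broadcastable (X, Y, Z) voxel-centre coordinate arrays."""
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)),
                           indexing="ij", sparse=True)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> Triple:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def contains_point(self, point_mm) -> bool:
        """True if a world point lies within the grid's bounding box."""
        for a in range(3):
            lo = self.origin[a]
            hi = lo + self.shape[a] * self.spacing[a]
            if not (lo <= point_mm[a] <= hi):
                return False
        return True
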