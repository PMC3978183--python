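"""Reconstruction-grid geometry.

All physical coordinates are millimetres in a frame whose origin is the
isocenter (the camera's center of rotation). Voxel indices are 0-based and
voxel *centers* sit at ``(i + 0.5 - n/2) * voxel_mm``, so the isocenter lies
at the geometric center of the grid (between the four central voxels for an
even matrix). Arrays are indexed ``[row, col] == [y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Matrix sizes of the acquisition/rebinning ladder (0.9 / 1.8 / 3.6 mm voxels
#: over a 230.4 mm field of view).
MATRIX_LADDER = (256, 128, 64)


@dataclass(frozen=True)
class GridSpec:
    """Square isotropic voxel grid centred on the isocenter.

    Parameters
    ----------
    n_xy:
        Voxels per side.
    voxel_mm:
        Isotropic voxel edge in mm.
    """

    n_xy: int
    voxel_mm: float

    def __post_init__(self) -> None:
        if self.n_xy < 4:
            raise ValueError(f"n_xy={self.n_xy} too small for a tomographic grid")
        if not np.isfinite(self.voxel_mm) or self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")

    @property
    def fov_mm(self) -> float:
        """Field-of-view edge length in mm (``n_xy * voxel_mm``)."""
        return self.n_xy * self.voxel_mm

    @classmethod
    def from_fov(cls, n_xy: int, fov_mm: float) -> "GridSpec":
        return cls(n_xy, fov_mm / n_xy)

    def centers_mm(self) -> np.ndarray:
        """1-D array of voxel-center coordinates along either axis (mm)."""
        n = self.n_xy
        return (np.arange(n) + 0.5 - n / 2.0) * self.voxel_mm

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) voxel-center coordinate arrays, shape (n, n); row=y, col=x."""
        c = self.centers_mm()
        return np.meshgrid(c, c, indexing="xy")

    def mm_to_index(self, coord_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index for physical coordinates."""
        return np.asarray(coord_mm) / self.voxel_mm + self.n_xy / 2.0 - 0.5

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx) + 0.5 - self.n_xy / 2.0) * self.voxel_mm

    def radius_map_mm(self) -> np.ndarray:
        X, Y = self.meshgrid_mm()
        return np.hypot(X, Y)

    def rebin(self, factor: int) -> "GridSpec":
        if self.n_xy % factor:
            raise ValueError(f"matrix {self.n_xy} not divisible by {factor}")
        return GridSpec(self.n_xy // factor, self.voxel_mm * factor)


#: The acquisition grid of the study: 256 x 256 at 0.9 mm (230.4 mm FOV).
ACQUISITION_GRID = GridSpec(256, 0.9)
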