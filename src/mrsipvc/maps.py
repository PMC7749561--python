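"""Shared in-memory containers for gridded metabolite data.

Arrays are indexed ``(x, y, z)``. The native MRSI grid of the default
acquisition is 44 x 44 in-plane with two 10 mm slices; the anatomical grid
covers the same slab at 1 mm isotropic resolution (220 x 220 x 20). Missing
(filtered or never-acquired) voxels are marked with quiet NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ShapeError

#: Missing-value marker used throughout the package.
MISSING = np.nan


@dataclass
class MetaboliteMap:
    """Per-metabolite values (ratio over tCr, unitless) on a named grid.

    Parameters
    ----------
    values:
        Float field shaped ``(nx, ny, nz)``; NaN marks missing voxels.
    metabolite:
        Metabolite name, e.g. ``"Glu"`` or ``"tNAA"``.
    grid:
        Grid label: ``"native"``, ``"anat"``, ``"reference"`` or a derived
        label such as ``"native_x4"``.
    voxel_size_mm:
        Cell size along each axis in millimetres.
    """

    values: np.ndarray
    metabolite: str
    grid: str = "native"
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError(
                f"metabolite map must be 3-D, got shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean field, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def with_values(self, values: np.ndarray, grid: str | None = None,
                    voxel_size_mm: tuple[float, float, float] | None = None
                    ) -> "MetaboliteMap":
        """Copy carrying new values (and optionally a new grid descriptor)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if grid is not None:
            out.grid = grid
        if voxel_size_mm is not None:
            out.voxel_size_mm = voxel_size_mm
        return out

    def copy(self) -> "MetaboliteMap":
        return replace(self, values=self.values.copy())
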