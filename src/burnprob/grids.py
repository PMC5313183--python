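"""Raster landscape container and terrain derivatives.

The analysis operates on a co-registered stack of per-cell layers on a
planar grid: fuel composition (area shares of pine, fir, broadleaf and
other species), stand age, topography (elevation, slope, aspect) and
human-activity covariates (population density, distance to the nearest
road and settlement).  Rows are indexed from the *lower-left* corner, so
``y`` increases with the row index; projected coordinates of a cell
center are ``(xll + (col + 0.5) * cell_size, yll + (row + 0.5) * cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

#: canonical fuel-type ordering; integer codes in ``fuel_class`` index this
FUEL_TYPES: Tuple[str, ...] = ("pine", "fir", "broadleaf", "others")

#: layers that vary in space only (no weather); used to build model matrices
SPATIAL_LAYERS: Tuple[str, ...] = (
    "prop_pine",
    "prop_fir",
    "prop_broadleaf",
    "prop_others",
    "dominant_age",
    "elevation",
    "slope",
    "aspect",
    "pop_density",
    "dist_road",
    "dist_settlement",
)


@dataclass
class LandscapeGrid:
    """Co-registered raster stack of landscape covariates.

    Distances are stored in kilometers, elevation in meters, slope and
    aspect in degrees (aspect clockwise from north in ``[1, 360]``, with
    flat cells flagged in ``flat`` and aspect set to 0 there).
    """

    cell_size: float  # meters
    prop_pine: np.ndarray
    prop_fir: np.ndarray
    prop_broadleaf: np.ndarray
    prop_others: np.ndarray
    dominant_age: np.ndarray
    elevation: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    pop_density: np.ndarray
    dist_road: np.ndarray
    dist_settlement: np.ndarray
    burnable: np.ndarray = None  # bool mask; default all True
    flat: np.ndarray = None  # bool mask of zero-gradient cells
    xll: float = 0.0
    yll: float = 0.0
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.elevation.shape
        if self.burnable is None:
            self.burnable = np.ones(shape, dtype=bool)
        if self.flat is None:
            self.flat = np.zeros(shape, dtype=bool)

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.elevation.shape

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size ** 2 / 1e4

    def cell_xy(self, row, col):
        """Projected coordinates (m) of cell centers."""
        x = self.xll + (np.asarray(col) + 0.5) * self.cell_size
        y = self.yll + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    # -- derived layers -----------------------------------------------
    @property
    def fuel_class(self) -> np.ndarray:
        """Integer fuel-type code per cell by the largest-proportion rule."""
        stack = np.stack(
            [self.prop_pine, self.prop_fir, self.prop_broadleaf, self.prop_others]
        )
        return np.argmax(stack, axis=0)

    def layer(self, name: str) -> np.ndarray:
        if name not in SPATIAL_LAYERS:
            raise KeyError(f"unknown layer {name!r}")
        return getattr(self, name)

    def validate(self) -> None:
        """Check layer invariants; raise ``ValueError`` on violation."""
        shape = self.shape
        for name in SPATIAL_LAYERS:
            if self.layer(name).shape != shape:
                raise ValueError(f"layer {name!r} shape mismatch")
        total = (
            self.prop_pine + self.prop_fir + self.prop_broadleaf + self.prop_others
        )
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("fuel proportions do not sum to 1")
        for name in ("dist_road", "dist_settlement", "pop_density", "dominant_age"):
            if np.any(self.layer(name) < 0):
                raise ValueError(f"negative values in {name!r}")
        if np.any((self.slope < 0) | (self.slope >= 90)):
            raise ValueError("slope out of [0, 90)")
        nonflat = ~self.flat
        if np.any((self.aspect[nonflat] < 1) | (self.aspect[nonflat] > 360)):
            raise ValueError("aspect out of [1, 360] on non-flat cells")


def slope_aspect(elevation: np.ndarray, cell_size: float, flat_tol: float = 1e-9):
    """Slope and aspect from central differences of an elevation grid.

    Parameters
    ----------
    elevation
        Elevation in meters, row 0 at the south (lower-left origin).
    cell_size
        Grid spacing in meters.
    flat_tol
        Gradient magnitude (m/m) below which a cell is flagged flat.

    Returns
    -------
    slope : degrees in [0, 90)
    aspect : degrees clockwise from north in [1, 360]; 0 on flat cells
    flat : boolean mask of flat cells
    """
    elevation = np.asarray(elevation, dtype=float)
    if elevation.ndim != 2 or min(elevation.shape) < 2:
        raise ValueError("elevation must be a 2-D grid with at least 2 rows/cols")
    dz_dy, dz_dx = np.gradient(elevation, cell_size)  # rows increase northwards
    grad = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad))
    flat = grad < flat_tol
    # aspect: compass bearing of the downslope direction, reported in
    # whole degrees 1..360 (the DEM convention; due north is 360)
    aspect = np.rint(np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0)
    aspect[aspect == 0.0] = 360.0
    aspect[flat] = 0.0
    return slope, aspect, flat
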