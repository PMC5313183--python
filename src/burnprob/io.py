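"""Plain-text formats: Esri ASCII rasters, weather CSV, fire catalogues.

Rasters use the 6-line Esri ASCII grid header (``ncols``, ``nrows``,
``xllcorner``, ``yllcorner``, ``cellsize``, ``NODATA_value``).  The first
data row in the file is the *northernmost* row; in memory row 0 is the
*southernmost*, so arrays are flipped on read/write.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .grids import SPATIAL_LAYERS, LandscapeGrid

log = logging.getLogger(__name__)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path) -> Tuple[np.ndarray, Dict[str, float]]:
    """Read an Esri ASCII grid.

    Returns the array with row 0 at the south and a header dict.  NODATA
    cells become ``numpy.nan``.  Malformed headers raise ``ValueError``
    naming the offending line.
    """
    path = Path(path)
    header: Dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, key in enumerate(_HEADER_KEYS):
        if i >= len(lines):
            raise ValueError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise ValueError(
                f"{path}: line {i + 1}: expected '{key} <value>', got {lines[i]!r}"
            )
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: bad value {parts[1]!r}") from exc
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = np.loadtxt(lines[len(_HEADER_KEYS):], ndmin=2)
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    body[body == header["nodata_value"]] = np.nan
    return np.flipud(body).copy(), header


def write_ascii_grid(path, array: np.ndarray, cell_size: float,
                     xll: float = 0.0, yll: float = 0.0,
                     nodata: float = -9999.0, fmt: str = "%.8g") -> None:
    """Write an array (row 0 at the south) as an Esri ASCII grid."""
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    nrows, ncols = arr.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {xll:.8g}\nyllcorner {yll:.8g}\n"
        f"cellsize {cell_size:.8g}\nNODATA_value {nodata:.8g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.flipud(out), fmt=fmt)


# ---------------------------------------------------------------------------
# landscape stacks

def write_landscape(grid: LandscapeGrid, directory) -> None:
    """Write every spatial layer of a landscape as ``<layer>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SPATIAL_LAYERS:
        write_ascii_grid(directory / f"{name}.asc", grid.layer(name),
                         grid.cell_size, grid.xll, grid.yll)
    write_ascii_grid(directory / "burnable.asc", grid.burnable.astype(float),
                     grid.cell_size, grid.xll, grid.yll, fmt="%d")


def read_landscape(directory) -> LandscapeGrid:
    directory = Path(directory)
    layers = {}
    header = None
    for name in SPATIAL_LAYERS:
        arr, header = read_ascii_grid(directory / f"{name}.asc")
        layers[name] = arr
    burnable_path = directory / "burnable.asc"
    burnable = None
    if burnable_path.exists():
        arr, _ = read_ascii_grid(burnable_path)
        burnable = arr > 0.5
    grid = LandscapeGrid(cell_size=header["cellsize"], burnable=burnable,
                         xll=header["xllcorner"], yll=header["yllcorner"],
                         **layers)
    from .grids import slope_aspect  # flat mask is derivable, not stored

    _, _, grid.flat = slope_aspect(grid.elevation, grid.cell_size)
    return grid


# ---------------------------------------------------------------------------
# weather

WEATHER_COLUMNS = ("date", "year", "month", "day", "doy",
                   "t_max", "t_avg", "rh", "precip", "wind_dir", "wind_max")


def write_weather(archive: pd.DataFrame, path) -> None:
    archive.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# fire catalogues

CATALOGUE_REQUIRED = ("date", "row", "col", "cause", "size_ha")


def write_fire_catalogue(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_fire_catalogue(path, landscape: Optional[LandscapeGrid] = None,
                        archive: Optional[pd.DataFrame] = None,
                        min_size: float = 0.0) -> Tuple[pd.DataFrame, int]:
    """Read and validate a fire catalogue CSV.

    Rows with non-positive or sub-minimum sizes, cells outside the
    landscape, or dates outside the weather archive span are dropped and
    counted (the registry this emulates contained invalid records too).

    Returns the clean events and the number of rows dropped.
    """
    df = pd.read_csv(path)
    missing = set(CATALOGUE_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    n0 = len(df)
    keep = df["size_ha"] > max(min_size, 0.0)
    if landscape is not None:
        keep &= (
            (df["row"] >= 0) & (df["row"] < landscape.n_rows)
            & (df["col"] >= 0) & (df["col"] < landscape.n_cols)
        )
    if archive is not None:
        valid_dates = set(archive["date"].astype(str))
        keep &= df["date"].astype(str).isin(valid_dates)
    dropped = int(n0 - keep.sum())
    if dropped:
        log.warning("dropped %d invalid catalogue rows of %d", dropped, n0)
    return df.loc[keep].reset_index(drop=True), dropped
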