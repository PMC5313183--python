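"""Surface fire-spread rate and cellular-automaton propagation.

The head-fire rate of spread (m/min) follows the multiplicative form
used for Chinese forest systems::

    R = R0 * Kf * Kw * Kt
    R0 = a*T + b*v + c*(1 - h) - d

where ``T`` is the daily maximum temperature (deg C), ``v`` the maximum
wind speed (m/s) and ``h`` relative humidity as a fraction.  ``Kf`` is a
fuel-type multiplier in [0.8, 1.8], ``Kw = exp(0.1783 v)`` the wind
multiplier and ``Kt = exp(3.533 tan(phi)^1.2)`` the slope multiplier for
upslope angle ``phi``.  A negative ``R0`` is clamped to zero: no spread.

Spatial propagation runs on the 8-neighborhood of the raster as a
fire-arrival-time computation (a discrete-event queue equivalent to
Dijkstra's algorithm on the cell graph): the travel time across an edge
is the inter-center distance divided by the mean of the two cells' rates.
Cells ignite in arrival-time order until the burned area reaches the
stochastically drawn target size, which stands in for suppression.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Tuple

import numpy as np

from .grids import FUEL_TYPES, LandscapeGrid

#: default fuel multipliers, within the empirical [0.8, 1.8] band and
#: ordered by flammability: pine and fir burn readily, broadleaf resists.
DEFAULT_KF: Dict[str, float] = {
    "pine": 1.2,
    "fir": 1.0,
    "others": 0.9,
    "broadleaf": 0.8,
}


@dataclass
class SpreadParams:
    """Coefficients of the spread-rate model (all overridable)."""

    a: float = 0.03  # 1/degC * m/min
    b: float = 0.05  # s/m * m/min
    c: float = 0.01  # m/min
    d: float = 0.3   # m/min
    wind_coef: float = 0.1783  # s/m
    slope_coef: float = 3.533
    slope_exp: float = 1.2
    kf: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KF))

    def __post_init__(self) -> None:
        for fuel, value in self.kf.items():
            if fuel not in FUEL_TYPES:
                raise ValueError(f"unknown fuel type {fuel!r}")
            if not 0.8 <= value <= 1.8:
                raise ValueError(f"Kf[{fuel}]={value} outside [0.8, 1.8]")
        for name in ("a", "b", "c", "d", "wind_coef", "slope_coef", "slope_exp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite spread coefficient {name}")

    def kf_array(self) -> np.ndarray:
        return np.array([self.kf[f] for f in FUEL_TYPES])


class SpreadRate(NamedTuple):
    r: float
    r0: float
    kw: float
    kt: float
    kf: float


def spread_rate(t_max: float, wind: float, rh: float, slope_deg: float,
                fuel_class: str, params: SpreadParams | None = None) -> SpreadRate:
    """Spread rate and its components for one cell.

    ``rh`` is relative humidity in percent (converted internally to a
    fraction).  ``slope_deg`` must be below 90; steeper input is rejected.
    """
    params = params or SpreadParams()
    if not 0 <= slope_deg < 90:
        raise ValueError(f"slope {slope_deg} deg outside [0, 90)")
    if not 0 <= rh <= 100:
        raise ValueError(f"relative humidity {rh} outside [0, 100] percent")
    h = rh / 100.0
    r0 = params.a * t_max + params.b * wind + params.c * (1.0 - h) - params.d
    r0 = max(r0, 0.0)
    kw = math.exp(params.wind_coef * wind)
    kt = math.exp(params.slope_coef * math.tan(math.radians(slope_deg)) ** params.slope_exp)
    kf = params.kf[fuel_class]
    return SpreadRate(r0 * kf * kw * kt, r0, kw, kt, kf)


# 8-neighborhood offsets and center-to-center distances (in cell units)
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NDIST = [math.sqrt(2), 1.0, math.sqrt(2), 1.0, 1.0, math.sqrt(2), 1.0, math.sqrt(2)]


def base_rate_grid(landscape: LandscapeGrid, t_max: float, wind: float,
                   rh: float, params: SpreadParams,
                   isotropic_slope: bool = False) -> np.ndarray:
    """Per-cell spread rate before the slope term (directional mode) or
    including the cell's scalar-slope ``Kt`` (isotropic mode).

    Non-burnable cells get rate 0 and act as barriers.
    """
    if not 0 <= rh <= 100:
        raise ValueError("relative humidity must be in [0, 100] percent")
    h = rh / 100.0
    r0 = params.a * t_max + params.b * wind + params.c * (1.0 - h) - params.d
    r0 = max(r0, 0.0)
    kw = math.exp(params.wind_coef * wind)
    rate = r0 * kw * params.kf_array()[landscape.fuel_class]
    if isotropic_slope:
        tan_phi = np.tan(np.radians(np.clip(landscape.slope, 0, 89.9)))
        rate = rate * np.exp(params.slope_coef * tan_phi ** params.slope_exp)
    return np.where(landscape.burnable, rate, 0.0)


def simulate_fire(ignition: Tuple[int, int], landscape: LandscapeGrid,
                  t_max: float, wind: float, rh: float, target_size_ha: float,
                  params: SpreadParams | None = None,
                  isotropic_slope: bool = False,
                  base_rates: np.ndarray | None = None):
    """Propagate one fire from ``ignition`` until the burned area reaches
    ``target_size_ha`` or no spreadable neighbor remains.

    In the default (directional) mode the slope multiplier is applied per
    edge using the upslope angle from the elevation difference between the
    two cells; flat or downslope edges get ``Kt = 1``.  With
    ``isotropic_slope=True`` the cell's scalar slope enters each cell's
    own rate instead.

    Returns ``(burned, realized_size_ha)`` where ``burned`` lists cells in
    arrival order.  An ignition on a non-burnable cell yields an empty
    burned set and size 0 (the event is still recorded by the caller).
    """
    params = params or SpreadParams()
    nrows, ncols = landscape.shape
    r, c = ignition
    if not (0 <= r < nrows and 0 <= c < ncols):
        raise ValueError(f"ignition {ignition} outside grid")
    if target_size_ha < landscape.cell_area_ha:
        raise ValueError("target size below one cell area")
    if not landscape.burnable[r, c]:
        return [], 0.0
    if base_rates is None:
        base_rates = base_rate_grid(landscape, t_max, wind, rh, params,
                                    isotropic_slope)
    cell_area = landscape.cell_area_ha
    cell_m = landscape.cell_size
    elev = landscape.elevation
    directional = not isotropic_slope

    arrival = {}  # (row, col) -> arrival time (min)
    burned: List[Tuple[int, int]] = []
    heap = [(0.0, r, c)]
    while heap:
        t, i, j = heapq.heappop(heap)
        if (i, j) in arrival:
            continue
        arrival[(i, j)] = t
        burned.append((i, j))
        if len(burned) * cell_area >= target_size_ha:
            break
        ri = base_rates[i, j]
        if ri <= 0.0:
            continue
        for (di, dj), dist in zip(_NEIGHBORS, _NDIST):
            ni, nj = i + di, j + dj
            if not (0 <= ni < nrows and 0 <= nj < ncols) or (ni, nj) in arrival:
                continue
            rj = base_rates[ni, nj]
            if rj <= 0.0:
                continue  # R = 0 cells are barriers and never ignite
            rate = 0.5 * (ri + rj)
            dist_m = dist * cell_m
            if directional:
                rise = elev[ni, nj] - elev[i, j]
                if rise > 0.0:
                    tan_phi = rise / dist_m
                    rate *= math.exp(params.slope_coef * tan_phi ** params.slope_exp)
            heapq.heappush(heap, (t + dist_m / rate, ni, nj))
    return burned, len(burned) * cell_area
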