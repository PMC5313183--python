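"""Stochastic burn-probability (BP) engine.

Each replicate "run" is one simulated fire year: monthly ignition counts
are Poisson draws with the historical monthly means; each ignition gets
a uniform date within its month, a weather day drawn uniformly from the
archive days within +/-10 calendar days of that date (circularly across
the year boundary, over all archive years), a location drawn from the
day's ignition-probability surface by acceptance-rejection, and a target
size drawn from the fire-size ensemble with a bootstrap residual.  The
fire then spreads by the cellular automaton until it reaches the target.
Per-cell BP is the burn count over all runs divided by the number of
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import ks_2samp

from .grids import LandscapeGrid
from .ignition import spatial_linear_predictor
from .size import SizeEnsemble, draw_stochastic_size
from .spread import SpreadParams, base_rate_grid, simulate_fire

#: month lengths of the 365-day (no-leap) simulation calendar
MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_START = np.concatenate([[0], np.cumsum(MONTH_DAYS)])


def day_of_year(month: int, day: int) -> int:
    """1-based day of year in the no-leap calendar."""
    return int(_MONTH_START[month - 1] + day)


@dataclass
class SimulationConfig:
    """Knobs of the BP simulation."""

    n_runs: int = 10_000
    monthly_rates: Sequence[float] = field(
        default_factory=lambda: [0.0] * 12)  # expected ignitions per month
    half_width: int = 10          # weather-window half width, days
    min_size_ha: float = 0.3      # smallest registry fire size
    isotropic_slope: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if len(self.monthly_rates) != 12 or any(r < 0 for r in self.monthly_rates):
            raise ValueError("monthly_rates must be 12 non-negative values")


# ---------------------------------------------------------------------------
# elementary samplers

def sample_monthly_counts(rates: Sequence[float],
                          rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson ignition counts for the 12 months."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (12,) or np.any(rates < 0):
        raise ValueError("rates must be 12 non-negative values")
    return rng.poisson(rates)


def sample_ignition_date(month: int, rng: np.random.Generator) -> int:
    """Uniform day-of-month draw (no-leap calendar)."""
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    return int(rng.integers(1, MONTH_DAYS[month - 1] + 1))


def sample_ignition_cell(surface: np.ndarray,
                         rng: np.random.Generator) -> Tuple[int, int]:
    """Acceptance-rejection draw of a cell with probability proportional
    to the surface value, using the maximum cell value as envelope."""
    surface = np.asarray(surface, dtype=float)
    smax = surface.max()
    if not smax > 0:
        raise ValueError("ignition surface has no positive cell")
    nrows, ncols = surface.shape
    while True:
        idx = rng.integers(0, surface.size, size=64)
        u = rng.random(64)
        flat = surface.reshape(-1)[idx]
        ok = u * smax < flat
        if ok.any():
            k = int(idx[ok][0])
            return k // ncols, k % ncols


def weather_window_indices(archive: pd.DataFrame,
                           half_width: int = 10) -> Dict[int, np.ndarray]:
    """For each day-of-year, the archive row indices whose day-of-year is
    within ``half_width`` days circularly (wrapping across Dec/Jan)."""
    doy = archive["doy"].to_numpy(dtype=int)
    out = {}
    for d in range(1, 366):
        diff = np.abs(doy - d)
        circ = np.minimum(diff, 365 - diff)
        out[d] = np.nonzero(circ <= half_width)[0]
    return out


def draw_weather(doy: int, archive: pd.DataFrame, half_width: int = 10,
                 rng: Optional[np.random.Generator] = None,
                 _windows: Optional[Dict[int, np.ndarray]] = None) -> pd.Series:
    """Uniform draw among all archive days within the circular window."""
    rng = rng or np.random.default_rng(0)
    if _windows is not None:
        cand = _windows[doy]
    else:
        d = archive["doy"].to_numpy(dtype=int)
        diff = np.abs(d - doy)
        cand = np.nonzero(np.minimum(diff, 365 - diff) <= half_width)[0]
    if len(cand) == 0:
        raise ValueError(f"no archive days within {half_width} of doy {doy}")
    return archive.iloc[int(rng.choice(cand))]


# ---------------------------------------------------------------------------
# full simulation

@dataclass
class BPGrid:
    """Burn counts, burn probability and the simulated-fire catalogue."""

    counts: np.ndarray
    n_runs: int
    catalogue: pd.DataFrame

    @property
    def bp(self) -> np.ndarray:
        return self.counts / float(self.n_runs)


def run_simulation(landscape: LandscapeGrid, archive: pd.DataFrame,
                   ignition_coefs: Mapping[str, float],
                   size_model: Union[SizeEnsemble, "TrueSizeModel"],
                   config: SimulationConfig,
                   params: Optional[SpreadParams] = None) -> BPGrid:
    """Simulate ``config.n_runs`` replicate fire years and accumulate BP.

    ``ignition_coefs`` is a mapping of logistic coefficients (from a
    fitted :class:`~burnprob.ignition.LogisticFit` via ``coefficients()``
    or the generative truth).  ``size_model`` supplies stochastic target
    sizes; it is either a fitted :class:`~burnprob.size.SizeEnsemble` or
    any object with a ``draw(covariate_frame, rng)`` method.
    """
    params = params or SpreadParams()
    rng = np.random.default_rng(config.seed)
    nrows, ncols = landscape.shape
    counts = np.zeros((nrows, ncols), dtype=np.int64)

    # ignition counts and dates for every run, drawn up front
    all_counts = rng.poisson(np.asarray(config.monthly_rates, dtype=float),
                             size=(config.n_runs, 12))
    runs: List[int] = []
    months_l: List[int] = []
    for r, m in zip(*np.nonzero(all_counts)):
        k = all_counts[r, m]
        runs.extend([int(r)] * k)
        months_l.extend([int(m) + 1] * k)
    n_fires = len(runs)
    days = np.array([sample_ignition_date(m, rng) for m in months_l], dtype=int)
    doys = np.array([day_of_year(m, d) for m, d in zip(months_l, days)])

    windows = weather_window_indices(archive, config.half_width)
    widx = np.array([int(rng.choice(windows[d])) for d in doys], dtype=int) \
        if n_fires else np.empty(0, dtype=int)
    wdf = archive.iloc[widx].reset_index(drop=True)
    t_max_arr = wdf["t_max"].to_numpy(dtype=float) if n_fires else np.empty(0)
    wind_arr = wdf["wind_max"].to_numpy(dtype=float) if n_fires else np.empty(0)
    rh_arr = wdf["rh"].to_numpy(dtype=float) if n_fires else np.empty(0)

    # locations by acceptance-rejection against the day's surface; the
    # weather enters the linear predictor as a scalar offset, so only
    # proposed cells are evaluated (the envelope is the maximum cell
    # probability, attained at the maximal spatial predictor).
    lp = spatial_linear_predictor(landscape, ignition_coefs)
    lp = np.where(landscape.burnable, lp, -np.inf)
    lp_flat = lp.reshape(-1)
    lp_max = lp_flat.max()
    if not np.isfinite(lp_max):
        raise ValueError("no burnable cell with finite ignition predictor")
    offsets = np.zeros(n_fires)
    for name in ("t_avg", "rh", "precip", "t_max", "wind_max"):
        if name in ignition_coefs and n_fires:
            offsets += ignition_coefs[name] * wdf[name].to_numpy(dtype=float)
    cells = np.empty((n_fires, 2), dtype=int)
    for f in range(n_fires):
        off = offsets[f]
        pmax = expit(lp_max + off)
        while True:
            idx = rng.integers(0, lp_flat.size, size=64)
            u = rng.random(64)
            ok = u * pmax < expit(lp_flat[idx] + off)
            if ok.any():
                k = int(idx[ok][0])
                cells[f] = k // ncols, k % ncols
                break

    # target sizes, batched over all fires
    from .size import SIZE_VARIABLES
    cov = {}
    for name in SIZE_VARIABLES:
        if name in ("wind_max", "rh", "t_max"):
            cov[name] = wdf[name].to_numpy(dtype=float)
        else:
            cov[name] = landscape.layer(name)[cells[:, 0], cells[:, 1]]
    cov = pd.DataFrame(cov)
    # targets keep the registry floor; the spread itself cannot burn less
    # than the ignition cell, so the propagation target is additionally
    # floored at one cell area below
    if isinstance(size_model, SizeEnsemble):
        targets = draw_stochastic_size(size_model, cov, rng,
                                       min_size=config.min_size_ha)
    else:
        targets = np.maximum(size_model.draw(cov, rng), config.min_size_ha)
    spread_targets = np.maximum(targets, landscape.cell_area_ha)

    records = []
    rate_cache: Dict[int, np.ndarray] = {}
    for f in range(n_fires):
        key = int(widx[f])  # one archive day -> one rate grid
        if key not in rate_cache:
            if len(rate_cache) > 1024:
                rate_cache.clear()
            rate_cache[key] = base_rate_grid(
                landscape, t_max_arr[f], wind_arr[f], rh_arr[f], params,
                config.isotropic_slope)
        burned, realized = simulate_fire(
            (int(cells[f, 0]), int(cells[f, 1])), landscape, t_max_arr[f],
            wind_arr[f], rh_arr[f], float(spread_targets[f]),
            params, config.isotropic_slope, base_rates=rate_cache[key])
        for (i, j) in burned:
            counts[i, j] += 1
        records.append({
            "run": runs[f], "month": months_l[f], "day": int(days[f]),
            "doy": int(doys[f]), "row": int(cells[f, 0]),
            "col": int(cells[f, 1]), "target_ha": float(targets[f]),
            "realized_ha": float(realized), "n_cells": len(burned),
        })
    catalogue = pd.DataFrame(records, columns=[
        "run", "month", "day", "doy", "row", "col", "target_ha",
        "realized_ha", "n_cells"])
    return BPGrid(counts=counts, n_runs=config.n_runs, catalogue=catalogue)


# ---------------------------------------------------------------------------
# validation

def ks_two_sample(sizes_a: Sequence[float],
                  sizes_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def validate_against_history(historical_sizes: Sequence[float],
                             simulated_sizes: Sequence[float],
                             years_historical: float,
                             n_runs: int) -> Dict[str, float]:
    """KS comparison of size distributions plus annual burned-area check."""
    d, p = ks_two_sample(historical_sizes, simulated_sizes)
    hist = np.asarray(historical_sizes, dtype=float)
    sim = np.asarray(simulated_sizes, dtype=float)
    return {
        "ks_d": d,
        "ks_p": p,
        "annual_area_hist_ha": float(hist.sum() / years_historical),
        "annual_area_sim_ha": float(sim.sum() / n_runs),
        "mean_size_hist_ha": float(hist.mean()),
        "mean_size_sim_ha": float(sim.mean()),
    }
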