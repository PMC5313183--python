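"""Synthetic landscapes, weather archives and model-generated fire histories.

The generator emulates a subtropical, human-dominated mountain forest
county: a fragmented four-type fuel mosaic (pine / fir / broadleaf /
others) whose pine share declines above ~700 m elevation; a single
dominant valley traced by the road network, with settlements and
population concentrated at low elevation (a strong human-access
gradient); a 20-year daily weather archive with mild dry winters, hot
wet summers and a winter-spring fire season; and a fire catalogue
produced by the *same* ignition-and-spread machinery the analysis later
fits, so every downstream stage can be tested against known generative
parameters.

Marginal moments target the study system: mean fire size 5.41 ha
(sd 10.31), stand age 17.9 +/- 13.7 years, daily mean temperature
16.9 +/- 7.3 deg C, mean elevation ~640 m, ~11.25 ignitions per year of
which ~85% fall December-May.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from scipy.special import expit

from .grids import FUEL_TYPES, LandscapeGrid, slope_aspect
from .simulate import MONTH_DAYS, day_of_year, sample_ignition_date
from .spread import SpreadParams, simulate_fire

#: historical seasonality: 225 fires over 20 years, 191 of them in the
#: December-May fire season -> per-month Poisson means
DEC_MAY_RATE = 191 / (20 * 6)
OFF_SEASON_RATE = 34 / (20 * 6)
DEFAULT_MONTHLY_RATES = tuple(
    [DEC_MAY_RATE] * 5 + [OFF_SEASON_RATE] * 6 + [DEC_MAY_RATE])

#: generative logistic coefficients for daily ignition occurrence.
#: Fuel proportions live on [0, 1], so their coefficients are per full
#: sweep of composition; the settlement-distance coefficient (per km)
#: encodes the strong human-access gradient.
TRUE_IGNITION_COEFS: Dict[str, float] = {
    "const": -4.0,
    "prop_pine": 2.2,
    "prop_fir": 1.8,
    "prop_broadleaf": -0.9,
    "dominant_age": -0.03,
    "slope": -0.025,
    "aspect": -0.0015,
    "t_avg": -0.06,
    "rh": -0.09,
    "dist_settlement": -0.35,
}


@dataclass
class SynthConfig:
    """All knobs of the synthetic world; identical config + seed gives
    byte-identical outputs."""

    seed: int = 0
    years: int = 20
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 200.0  # m

    # terrain
    base_elevation: float = 170.0    # m, valley floor
    relief: float = 900.0            # m, valley-to-ridge rise
    roughness: float = 150.0         # m, amplitude of the fractal component
    spectral_beta: float = 2.3       # power-law exponent of the surface

    # fuel mosaic
    mean_patch_cells: float = 6.0
    pine_elev_threshold: float = 700.0  # m; pine thins out above this
    pine_elev_strength: float = 2.0
    age_mean: float = 17.92          # years
    age_sd: float = 13.72

    # human layers
    n_settlements: int = 8
    settlement_elev_scale: float = 150.0  # m, softmax temperature
    settlement_road_scale: float = 0.8    # km; towns hug the valley road
    pop_scale: float = 800.0         # people/km2 at a settlement
    pop_decay_km: float = 2.0
    pop_noise_sigma: float = 0.8

    # weather
    t_mean: float = 16.92
    t_seasonal_amp: float = 9.0
    t_ar: float = 0.7
    t_sigma: float = 2.2
    tmax_offset: float = 7.95
    tmax_sigma: float = 1.5
    rh_mean: float = 73.16
    rh_seasonal_amp: float = 6.0
    rh_temp_coupling: float = 0.8    # % RH drop per deg C warm anomaly
    rh_sigma: float = 8.5
    wet_prob_mar_sep: float = 0.45
    wet_prob_oct_feb: float = 0.18
    precip_gamma_shape: float = 0.7
    precip_mean_wet: float = 14.0    # mm per wet day, Mar-Sep
    precip_mean_dry: float = 12.5
    wind_mu: float = -0.06           # lognormal log-mean, m/s
    wind_sigma: float = 0.64
    first_year: int = 1991

    # generative fire process
    monthly_rates: Sequence[float] = field(
        default_factory=lambda: list(DEFAULT_MONTHLY_RATES))
    ignition_coefs: Dict[str, float] = field(
        default_factory=lambda: dict(TRUE_IGNITION_COEFS))
    size_b_pine: float = 2.6
    size_b_logpop: float = 0.42
    size_b_slope: float = 0.035
    size_sigma_log: float = 0.8
    mean_size_ha: float = 5.41
    min_size_ha: float = 0.3
    lightning_prob: float = 1.0 / 225.0
    spread: SpreadParams = field(default_factory=SpreadParams)

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("grid must be at least 16 x 16")


# ---------------------------------------------------------------------------
# terrain

def _fractal_surface(shape: Tuple[int, int], beta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-sd multiscale surface via spectral synthesis."""
    ny, nx = shape
    white = rng.standard_normal((ny, nx))
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC component
    amp = f ** (-beta / 2.0)
    surf = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    return (surf - surf.mean()) / surf.std()


def _valley_rows(config: SynthConfig, phase: float) -> np.ndarray:
    """Row coordinate of the valley axis at each column (float)."""
    x = np.arange(config.n_cols) / config.n_cols
    return (config.n_rows / 2.0
            + 0.22 * config.n_rows * np.sin(2.0 * np.pi * 1.2 * x + phase))


def gen_terrain(config: SynthConfig, rng: np.random.Generator):
    """Elevation, slope and aspect with one dominant valley.

    Elevation rises away from a sinuous valley axis and carries a
    power-law multiscale roughness.  Returns ``(elevation, slope,
    aspect, flat, valley_rows)``; the valley axis is reused for the road.
    """
    phase = float(rng.uniform(0, 2 * np.pi))
    valley = _valley_rows(config, phase)
    cols = np.arange(config.n_cols)
    path = np.column_stack([valley, cols]).astype(float)
    rr, cc = np.mgrid[0:config.n_rows, 0:config.n_cols]
    tree = cKDTree(path)
    d, _ = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    d = d.reshape(config.n_rows, config.n_cols)
    d_norm = d / max(d.max(), 1.0)
    fract = _fractal_surface((config.n_rows, config.n_cols),
                             config.spectral_beta, rng)
    elevation = (config.base_elevation
                 + config.relief * d_norm ** 0.85
                 + config.roughness * fract)
    # anchor the valley floor: nothing below the base elevation
    elevation = np.maximum(elevation, config.base_elevation)
    slope, aspect, flat = slope_aspect(elevation, config.cell_size)
    slope = np.clip(slope, 0.0, 89.0)
    return elevation, slope, aspect, flat, valley


# ---------------------------------------------------------------------------
# fuel mosaic

def gen_fuel_mosaic(config: SynthConfig, elevation: np.ndarray,
                    rng: np.random.Generator):
    """Voronoi-patch fuel mosaic with elevation-dependent pine share.

    Patches approximate survey subcompartments.  Each patch draws a
    dominant fuel type — pine preferentially below the elevation
    threshold — and Dirichlet composition concentrated on that type.
    Returns ``(props dict, dominant_age, patch_labels)``.
    """
    nrows, ncols = elevation.shape
    n_cells = nrows * ncols
    n_patches = max(4, int(round(n_cells / config.mean_patch_cells)))
    seed_idx = rng.choice(n_cells, size=n_patches, replace=False)
    seed_pts = np.column_stack([seed_idx // ncols, seed_idx % ncols]).astype(float)
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    tree = cKDTree(seed_pts)
    _, labels = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    labels = labels.reshape(nrows, ncols)

    # base dominant-type frequencies chosen so marginal mean composition
    # approximates pine 14% / fir 39% / broadleaf 18% / others 29%
    base_w = np.array([0.075, 0.47, 0.14, 0.315])
    patch_elev = np.bincount(labels.ravel(), weights=elevation.ravel(),
                             minlength=n_patches)
    patch_elev /= np.bincount(labels.ravel(), minlength=n_patches)
    excess = np.maximum(0.0, patch_elev - config.pine_elev_threshold) / 200.0
    w = np.tile(base_w, (n_patches, 1))
    w[:, 0] *= np.exp(-config.pine_elev_strength * excess)
    w /= w.sum(axis=1, keepdims=True)
    dom = np.array([rng.choice(4, p=w[i]) for i in range(n_patches)])
    alpha = np.full((n_patches, 4), 0.6)
    alpha[np.arange(n_patches), dom] = 4.0
    comp = np.empty((n_patches, 4))
    for i in range(n_patches):
        comp[i] = rng.dirichlet(alpha[i])
    props = {f"prop_{name}": comp[labels, k]
             for k, name in enumerate(FUEL_TYPES)}

    shape_k = (config.age_mean / config.age_sd) ** 2
    scale = config.age_sd ** 2 / config.age_mean
    patch_age = rng.gamma(shape_k, scale, size=n_patches)
    return props, patch_age[labels], labels


# ---------------------------------------------------------------------------
# human activity

def gen_human_layers(config: SynthConfig, elevation: np.ndarray,
                     valley: np.ndarray, rng: np.random.Generator):
    """Valley-following road, low-elevation settlements, and the derived
    distance (km) and population-density layers."""
    nrows, ncols = elevation.shape
    road = np.zeros((nrows, ncols), dtype=bool)
    rows = np.clip(np.round(valley).astype(int), 0, nrows - 1)
    for c in range(ncols):
        road[rows[c], c] = True
        if c:  # connect vertical jumps so the polyline is 8-connected
            lo, hi = sorted((rows[c - 1], rows[c]))
            road[lo:hi + 1, c] = True

    dist_road = distance_transform_edt(~road, sampling=config.cell_size) / 1000.0

    # settlements string out along the valley road at low elevation, the
    # way towns follow the contours of a mountain valley
    logits = (-(elevation - elevation.min()) / config.settlement_elev_scale
              - dist_road / config.settlement_road_scale)
    prob = np.exp(logits.ravel())
    prob /= prob.sum()
    settle_idx = rng.choice(elevation.size, size=config.n_settlements,
                            replace=False, p=prob)
    settlement = np.zeros((nrows, ncols), dtype=bool)
    settlement.ravel()[settle_idx] = True

    dist_settlement = distance_transform_edt(
        ~settlement, sampling=config.cell_size) / 1000.0
    noise = rng.normal(0.0, config.pop_noise_sigma, size=elevation.shape)
    pop = config.pop_scale * np.exp(-dist_settlement / config.pop_decay_km
                                    + noise - config.pop_noise_sigma ** 2 / 2)
    return pop, dist_road, dist_settlement, settlement


# ---------------------------------------------------------------------------
# weather

_SEASON_PEAK_DOY = 197  # mid-July warmth peak


def gen_weather(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily archive over ``config.years`` no-leap years.

    Temperature follows a sinusoidal climatology plus AR(1) anomalies;
    RH tracks the wet season and dips with warm anomalies; precipitation
    is a seasonal Bernoulli-Gamma mixture placing ~80% of rain in
    March-September; wind speed is lognormal with uniform 16-sector
    direction.
    """
    n_days = config.years * 365
    doy = np.tile(np.arange(1, 366), config.years)
    season = np.cos(2 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.0)

    anom = np.empty(n_days)
    innov = rng.normal(0.0, config.t_sigma, size=n_days)
    anom[0] = innov[0] / np.sqrt(1 - config.t_ar ** 2)
    for i in range(1, n_days):
        anom[i] = config.t_ar * anom[i - 1] + innov[i]
    t_avg = config.t_mean + config.t_seasonal_amp * season + anom
    gap = np.maximum(0.3, config.tmax_offset
                     + rng.normal(0.0, config.tmax_sigma, size=n_days))
    t_max = t_avg + gap

    rh = (config.rh_mean + config.rh_seasonal_amp * season
          - config.rh_temp_coupling * anom
          + rng.normal(0.0, config.rh_sigma, size=n_days))
    rh = np.clip(rh, 0.0, 100.0)

    month = np.searchsorted(np.cumsum(MONTH_DAYS), (doy - 1) % 365,
                            side="right") + 1
    wet_season = (month >= 3) & (month <= 9)
    p_wet = np.where(wet_season, config.wet_prob_mar_sep,
                     config.wet_prob_oct_feb)
    is_wet = rng.random(n_days) < p_wet
    mean_amt = np.where(wet_season, config.precip_mean_wet,
                        config.precip_mean_dry)
    amount = rng.gamma(config.precip_gamma_shape,
                       mean_amt / config.precip_gamma_shape)
    precip = np.where(is_wet, amount, 0.0)

    wind_max = rng.lognormal(config.wind_mu, config.wind_sigma, size=n_days)
    wind_dir = rng.integers(1, 17, size=n_days)

    day_in_month = (doy - 1) % 365 - _cum_month_start(month)
    years = config.first_year + np.repeat(np.arange(config.years), 365)
    dates = [f"{y:04d}-{m:02d}-{d:02d}"
             for y, m, d in zip(years, month, day_in_month + 1)]
    return pd.DataFrame({
        "date": dates, "year": years, "month": month,
        "day": day_in_month + 1, "doy": doy, "t_max": t_max, "t_avg": t_avg,
        "rh": rh, "precip": precip, "wind_dir": wind_dir,
        "wind_max": wind_max,
    })


def _cum_month_start(month: np.ndarray) -> np.ndarray:
    starts = np.concatenate([[0], np.cumsum(MONTH_DAYS)[:-1]])
    return starts[month - 1]


# ---------------------------------------------------------------------------
# generative fire size model

@dataclass
class TrueSizeModel:
    """Known generative model for final fire size (ha): lognormal around a
    linear predictor in pine share, population and slope.

    Fuel (pine share) is the leading driver, population density second —
    the structure the size analysis is expected to recover.
    """

    b0: float
    b_pine: float
    b_logpop: float
    b_slope: float
    sigma: float
    min_size: float = 0.3

    def mu(self, cov: pd.DataFrame) -> np.ndarray:
        return (self.b0
                + self.b_pine * cov["prop_pine"].to_numpy(dtype=float)
                + self.b_logpop * np.log1p(cov["pop_density"].to_numpy(dtype=float))
                + self.b_slope * cov["slope"].to_numpy(dtype=float))

    def draw(self, cov: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        mu = self.mu(cov)
        size = np.exp(mu + self.sigma * rng.standard_normal(len(mu)))
        return np.maximum(size, self.min_size)


def calibrate_true_size_model(landscape: LandscapeGrid,
                              config: SynthConfig) -> TrueSizeModel:
    """Fix the size-model intercept so the landscape-marginal mean size
    equals ``config.mean_size_ha`` (lognormal mean identity)."""
    cov = pd.DataFrame({
        "prop_pine": landscape.prop_pine.ravel(),
        "pop_density": landscape.pop_density.ravel(),
        "slope": landscape.slope.ravel(),
    })
    model = TrueSizeModel(0.0, config.size_b_pine, config.size_b_logpop,
                          config.size_b_slope, config.size_sigma_log,
                          config.min_size_ha)
    lin = model.mu(cov)
    b0 = (np.log(config.mean_size_ha) - config.size_sigma_log ** 2 / 2
          - lin.mean() - lin.var() / 2)
    model.b0 = float(b0)
    return model


# ---------------------------------------------------------------------------
# assembly

def generate_landscape(config: SynthConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> LandscapeGrid:
    """Generate the full co-registered layer stack."""
    rng = rng or np.random.default_rng(config.seed)
    elevation, slope, aspect, flat, valley = gen_terrain(config, rng)
    props, age, labels = gen_fuel_mosaic(config, elevation, rng)
    pop, dist_road, dist_settlement, settlement = gen_human_layers(
        config, elevation, valley, rng)
    grid = LandscapeGrid(
        cell_size=config.cell_size, dominant_age=age, elevation=elevation,
        slope=slope, aspect=aspect, pop_density=pop, dist_road=dist_road,
        dist_settlement=dist_settlement, burnable=~settlement, flat=flat,
        meta={"patch_labels": labels, "valley": valley,
              "settlement": settlement},
        **props)
    grid.validate()
    return grid


@dataclass
class SyntheticWorld:
    """A landscape, its weather archive, the generative truth, and the
    model-generated fire history."""

    config: SynthConfig
    landscape: LandscapeGrid
    archive: pd.DataFrame
    size_model: TrueSizeModel
    fires: pd.DataFrame


def gen_fire_history(landscape: LandscapeGrid, archive: pd.DataFrame,
                     config: SynthConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Fire catalogue generated by the same ignition + spread machinery
    the simulator uses, with the true (known) parameters.

    Each event records its registry size (the drawn suppression size,
    floored at the minimum registry size) and the number of grid cells
    its spread actually covered.
    """
    if landscape.n_cells == 0:
        raise ValueError("empty landscape")
    size_model = calibrate_true_size_model(landscape, config)
    coefs = config.ignition_coefs
    from .ignition import spatial_linear_predictor, weather_offset

    lp = spatial_linear_predictor(landscape, coefs)
    lp = np.where(landscape.burnable, lp, -np.inf)
    lp_flat = lp.reshape(-1)
    lp_max = lp_flat.max()
    nrows, ncols = landscape.shape
    by_year_doy = {(int(y), int(d)): i for i, (y, d) in
                   enumerate(zip(archive["year"], archive["doy"]))}
    records: List[dict] = []
    rates = np.asarray(config.monthly_rates, dtype=float)
    for year in sorted(archive["year"].unique()):
        counts = rng.poisson(rates)
        for m in range(1, 13):
            for _ in range(int(counts[m - 1])):
                day = sample_ignition_date(m, rng)
                w = archive.iloc[by_year_doy[(int(year), day_of_year(m, day))]]
                off = weather_offset(coefs, w)
                pmax = expit(lp_max + off)
                while True:
                    idx = rng.integers(0, lp_flat.size, size=64)
                    u = rng.random(64)
                    ok = u * pmax < expit(lp_flat[idx] + off)
                    if ok.any():
                        k = int(idx[ok][0])
                        row, col = k // ncols, k % ncols
                        break
                cov = pd.DataFrame({
                    "prop_pine": [landscape.prop_pine[row, col]],
                    "pop_density": [landscape.pop_density[row, col]],
                    "slope": [landscape.slope[row, col]],
                })
                size = float(size_model.draw(cov, rng)[0])
                burned, _ = simulate_fire(
                    (row, col), landscape, float(w["t_max"]),
                    float(w["wind_max"]), float(w["rh"]),
                    max(size, landscape.cell_area_ha), config.spread)
                u = rng.random()
                if u < config.lightning_prob:
                    cause = "lightning"
                elif u < config.lightning_prob + 0.714:
                    cause = "human"
                else:
                    cause = "unknown"
                x, y = landscape.cell_xy(row, col)
                records.append({
                    "date": str(w["date"]), "year": int(year), "month": m,
                    "day": int(day), "row": row, "col": col,
                    "x": float(x), "y": float(y), "cause": cause,
                    "size_ha": size, "n_cells": max(len(burned), 0),
                })
    return pd.DataFrame(records, columns=[
        "date", "year", "month", "day", "row", "col", "x", "y", "cause",
        "size_ha", "n_cells"])


def generate_world(config: SynthConfig) -> SyntheticWorld:
    """One call: landscape, archive, calibrated size truth, fire history.

    All randomness flows from ``config.seed`` through independent child
    streams, so identical configs give byte-identical worlds.
    """
    ss = np.random.SeedSequence(config.seed)
    r_land, r_weather, r_fires = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    landscape = generate_landscape(config, r_land)
    archive = gen_weather(config, r_weather)
    size_model = calibrate_true_size_model(landscape, config)
    fires = gen_fire_history(landscape, archive, config, r_fires)
    return SyntheticWorld(config=config, landscape=landscape,
                          archive=archive, size_model=size_model,
                          fires=fires)
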