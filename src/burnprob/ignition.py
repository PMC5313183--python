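"""Binary logistic model of daily fire-ignition occurrence.

Ignition records (label 1) are contrasted with pseudo-absence points
(label 0) sampled uniformly over burnable cells but kept farther than
the ignitions' mean nearest-neighbor distance from every ignition.
Covariates mix static landscape layers with the weather of the
(non-)ignition day.  Before fitting, strongly correlated covariates
(|Pearson r| > 0.4) are screened so that only one of each such pair
enters the model.  Goodness of fit is summarized by the Cox & Snell and
Nagelkerke pseudo-R2 and the ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm

from .grids import LandscapeGrid

#: covariate set of the final occurrence model ("others" is the fuel
#: baseline and is left out to avoid perfect collinearity)
OCCURRENCE_VARIABLES: Tuple[str, ...] = (
    "prop_pine", "prop_fir", "prop_broadleaf", "dominant_age",
    "slope", "aspect", "t_avg", "rh", "dist_settlement",
)

#: full candidate set offered to the collinearity screen
CANDIDATE_VARIABLES: Tuple[str, ...] = (
    "prop_pine", "prop_fir", "prop_broadleaf", "dominant_age",
    "elevation", "slope", "aspect", "precip", "t_avg", "rh",
    "pop_density", "dist_road", "dist_settlement",
)

SPATIAL_VARIABLES = tuple(v for v in CANDIDATE_VARIABLES
                          if v not in ("t_avg", "rh", "precip"))


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer."""


# ---------------------------------------------------------------------------
# pseudo-absence sampling

def mean_nn_distance(points: np.ndarray) -> float:
    """Mean distance from each point to its nearest other point (meters)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValueError("need at least 2 points for nearest-neighbor distance")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return float(dist[:, 1].mean())


def sample_nonignitions(ignition_xy: np.ndarray, landscape: LandscapeGrid,
                        n: int, rng: np.random.Generator,
                        min_dist: Optional[float] = None,
                        mask: Optional[np.ndarray] = None,
                        max_tries: int = 1000) -> pd.DataFrame:
    """Sample ``n`` pseudo-absence cells uniformly over the mask, each at
    least ``min_dist`` meters from every ignition (rejection sampling).

    ``min_dist`` defaults to the ignitions' mean nearest-neighbor
    distance.  Raises ``RuntimeError`` with a diagnostic if the mask
    cannot accommodate the exclusion discs within the retry cap.
    """
    ignition_xy = np.atleast_2d(np.asarray(ignition_xy, dtype=float))
    if min_dist is None:
        min_dist = mean_nn_distance(ignition_xy)
    if mask is None:
        mask = landscape.burnable
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise RuntimeError("empty sampling mask")
    tree = cKDTree(ignition_xy)
    out_rows: List[int] = []
    out_cols: List[int] = []
    for _ in range(max_tries):
        need = n - len(out_rows)
        if need <= 0:
            break
        idx = rng.integers(0, len(rows), size=max(4 * need, 16))
        x, y = landscape.cell_xy(rows[idx], cols[idx])
        if min_dist > 0:
            d, _ = tree.query(np.column_stack([x, y]))
            ok = d >= min_dist
        else:
            ok = np.ones(len(idx), dtype=bool)
        out_rows.extend(rows[idx[ok]][:need])
        out_cols.extend(cols[idx[ok]][:need])
    if len(out_rows) < n:
        raise RuntimeError(
            f"could only place {len(out_rows)}/{n} pseudo-absences at "
            f"min_dist={min_dist:.0f} m; mask too small for the exclusion discs"
        )
    x, y = landscape.cell_xy(np.array(out_rows), np.array(out_cols))
    return pd.DataFrame({"row": out_rows, "col": out_cols, "x": x, "y": y})


def build_occurrence_sample(landscape: LandscapeGrid, archive: pd.DataFrame,
                            fires: pd.DataFrame, rng: np.random.Generator,
                            n_non: Optional[int] = None,
                            min_dist: Optional[float] = None) -> pd.DataFrame:
    """Assemble the labeled presence/pseudo-absence covariate table.

    Ignition rows take the weather of their recorded date; each
    pseudo-absence gets a uniformly drawn archive day (the registry pairs
    ignition and non-ignition days symmetrically, but no particular day
    attaches to an absence).
    """
    if n_non is None:
        n_non = len(fires)
    x, y = landscape.cell_xy(fires["row"].to_numpy(), fires["col"].to_numpy())
    non = sample_nonignitions(np.column_stack([x, y]), landscape, n_non, rng,
                              min_dist=min_dist)
    weather_by_date = archive.set_index(archive["date"].astype(str))
    rows = []
    for (label, pts, dates) in (
        (1, fires, fires["date"].astype(str).to_numpy()),
        (0, non, archive["date"].astype(str).sample(
            n=len(non), replace=True,
            random_state=int(rng.integers(0, 2**31))).to_numpy()),
    ):
        w = weather_by_date.loc[dates]
        for k, (_, pt) in enumerate(pts.iterrows()):
            r, c = int(pt["row"]), int(pt["col"])
            rec = {"label": label, "row": r, "col": c}
            for name in SPATIAL_VARIABLES:
                rec[name] = float(landscape.layer(name)[r, c])
            for name in ("t_avg", "rh", "precip", "t_max", "wind_max"):
                rec[name] = float(w.iloc[k][name])
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collinearity screening

def screen_collinearity(table: pd.DataFrame, threshold: float = 0.4,
                        priority: Optional[Mapping[str, float]] = None,
                        label: Optional[Sequence] = None):
    """Greedy screen keeping at most one of each |r| > threshold pair.

    Priority (larger = kept) defaults to the absolute Pearson correlation
    of each variable with ``label``; without either, earlier columns win.
    Constant columns have undefined correlations and are excluded with a
    warning.

    Returns ``(retained, dropped_pairs)`` where each dropped pair is
    ``(dropped, kept, r)``.
    """
    cols = list(table.columns)
    const = [c for c in cols if table[c].nunique() <= 1]
    for c in const:
        warnings.warn(f"constant column {c!r} excluded from screening")
    cols = [c for c in cols if c not in const]
    if priority is None:
        if label is not None:
            y = np.asarray(label, dtype=float)
            priority = {c: abs(np.corrcoef(table[c], y)[0, 1]) for c in cols}
        else:
            priority = {c: -i for i, c in enumerate(cols)}
    corr = table[cols].corr().abs()
    order = sorted(cols, key=lambda c: -priority[c])
    retained: List[str] = []
    dropped_pairs: List[Tuple[str, str, float]] = []
    for c in order:
        clash = [k for k in retained if corr.loc[c, k] > threshold]
        if clash:
            worst = max(clash, key=lambda k: corr.loc[c, k])
            dropped_pairs.append((c, worst, float(corr.loc[c, worst])))
        else:
            retained.append(c)
    retained = [c for c in cols if c in retained]  # original order
    return retained, dropped_pairs


# ---------------------------------------------------------------------------
# logistic fit

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``table`` mirrors the usual report: per-variable coefficient ``B``,
    its standard error, the Wald chi-square ``(B/SE)^2``, the p-value and
    the odds ratio ``Exp(B)``.
    """

    variables: List[str]
    params: pd.Series          # includes 'const'
    bse: pd.Series
    llf: float                 # fitted log-likelihood
    llnull: float              # intercept-only log-likelihood
    n: int

    @property
    def wald(self) -> pd.Series:
        return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> pd.Series:
        from scipy.stats import chi2
        return pd.Series(chi2.sf(self.wald, df=1), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "B": self.params, "SE": self.bse, "Wald": self.wald,
            "Sig": self.pvalues, "ExpB": self.odds_ratios,
        })

    def coefficients(self) -> Dict[str, float]:
        return dict(self.params)


def fit_logistic(sample: pd.DataFrame,
                 variables: Sequence[str] = OCCURRENCE_VARIABLES,
                 label: str = "label", maxiter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Fit the occurrence model by Newton iteration (via statsmodels).

    Raises ``SeparationError`` when the classes are (quasi-)separable:
    the iteration then drives some coefficient beyond |15|, where the
    likelihood has no interior maximum.
    """
    y = sample[label].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(sample[list(variables)].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter,
                                     tol=tol, disp=False)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if np.any(np.abs(res.params.drop("const", errors="ignore")) > 15) or \
            not np.all(np.isfinite(res.bse)):
        raise SeparationError(
            "diverging coefficients (|B| > 15): classes are separable")
    return LogisticFit(variables=list(variables), params=res.params,
                       bse=res.bse, llf=float(res.llf),
                       llnull=float(res.llnull), n=len(y))


@dataclass
class FitDiagnostics:
    cox_snell_r2: float
    nagelkerke_r2: float
    auc: Optional[float] = None


def pseudo_r2(fit: LogisticFit) -> FitDiagnostics:
    """Cox & Snell and Nagelkerke pseudo-R2 from the two log-likelihoods.

    CS = 1 - exp(2 (L0 - L1) / n);  Nagelkerke rescales CS by its
    maximum attainable value 1 - exp(2 L0 / n).
    """
    if fit.n <= 0:
        raise ValueError("empty sample")
    cs = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / fit.n)
    max_cs = 1.0 - np.exp(2.0 * fit.llnull / fit.n)
    return FitDiagnostics(cox_snell_r2=float(cs),
                          nagelkerke_r2=float(cs / max_cs))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC; equals the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# probability surfaces

def ignition_surface(landscape: LandscapeGrid,
                     coefficients: Mapping[str, float],
                     weather_day: Optional[Mapping[str, float]] = None,
                     mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-cell inverse-logit of the linear predictor for one day.

    ``coefficients`` maps variable names (plus ``const``) to logistic
    coefficients; weather variables are looked up in ``weather_day`` and
    applied uniformly (weather is spatially constant at this extent).
    Non-burnable cells are masked to probability 0.
    """
    lp = spatial_linear_predictor(landscape, coefficients)
    lp = lp + weather_offset(coefficients, weather_day)
    prob = expit(lp)
    if mask is None:
        mask = landscape.burnable
    return np.where(mask, prob, 0.0)


def spatial_linear_predictor(landscape: LandscapeGrid,
                             coefficients: Mapping[str, float]) -> np.ndarray:
    """The static (landscape-only) part of the logistic linear predictor."""
    lp = np.full(landscape.shape, float(coefficients.get("const", 0.0)))
    for name, beta in coefficients.items():
        if name == "const" or name in ("t_avg", "rh", "precip", "t_max",
                                       "wind_max"):
            continue
        lp += beta * landscape.layer(name)
    return lp


def weather_offset(coefficients: Mapping[str, float],
                   weather_day: Optional[Mapping[str, float]]) -> float:
    """Contribution of the day's weather to the linear predictor."""
    off = 0.0
    for name in ("t_avg", "rh", "precip", "t_max", "wind_max"):
        if name in coefficients:
            if weather_day is None:
                raise ValueError(f"weather covariate {name!r} needs a weather day")
            off += coefficients[name] * float(weather_day[name])
    return off


def rank_groups_by_odds(fit: LogisticFit,
                        grouping: Mapping[str, Sequence[str]]) -> List[str]:
    """Rank factor groups by their strongest per-unit odds ratio.

    Follows the practice of comparing estimated odds ratios directly: a
    group's score is the largest |B| (log odds per covariate unit) among
    its members present in the fit.  Unit-dependent by construction —
    fuel proportions live on [0, 1], so a full sweep of composition is
    one unit.
    """
    scores = {}
    for group, members in grouping.items():
        present = [m for m in members if m in fit.params.index]
        if present:
            scores[group] = max(abs(float(fit.params[m])) for m in present)
    return sorted(scores, key=lambda g: -scores[g])
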