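"""Random-forest ensemble for final fire size.

Fire size (ha) is strongly non-linear in its drivers, so it is modeled
with an ensemble of 10 random forests (1000 trees each), every member
trained on an independent random two-thirds subsample with the held-out
third used as its out-of-bag (OOB) test.  Reported variance explained,
permutation importance (%IncMSE) and predictions are averages over the
10 members; the pooled OOB residuals provide the stochastic component
added to predictions when the ensemble drives the simulator's
size-based termination rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grids import LandscapeGrid

#: covariates offered to the size model (weather refers to the fire day)
SIZE_VARIABLES: Tuple[str, ...] = (
    "prop_pine", "pop_density", "slope", "prop_broadleaf", "dist_road",
    "aspect", "dominant_age", "prop_fir", "dist_settlement",
    "wind_max", "rh", "t_max",
)


def build_size_sample(landscape: LandscapeGrid, archive: pd.DataFrame,
                      fires: pd.DataFrame) -> pd.DataFrame:
    """Per-fire response/covariate table from catalogue, layers, weather."""
    weather_by_date = archive.set_index(archive["date"].astype(str))
    w = weather_by_date.loc[fires["date"].astype(str).to_numpy()]
    rec = {"size_ha": fires["size_ha"].to_numpy(dtype=float)}
    rows = fires["row"].to_numpy(dtype=int)
    cols = fires["col"].to_numpy(dtype=int)
    for name in SIZE_VARIABLES:
        if name in ("wind_max", "rh", "t_max"):
            rec[name] = w[name].to_numpy(dtype=float)
        else:
            rec[name] = landscape.layer(name)[rows, cols]
    out = pd.DataFrame(rec)
    if (out["size_ha"] <= 0).any():
        raise ValueError("fire sizes must be positive")
    return out


def default_mtry(p: int) -> int:
    """Regression default: floor(p / 3), at least 1."""
    return max(1, p // 3)


def tune_mtry(sample: pd.DataFrame, ntree: int = 1000,
              variables: Sequence[str] = SIZE_VARIABLES,
              response: str = "size_ha", seed: int = 0) -> int:
    """Stepwise search for the mtry minimizing the bagging OOB MSE.

    Starts at the regression default ``floor(p/3)`` and walks outward in
    both directions while the OOB error keeps improving; ties resolve to
    the smaller mtry.  Deterministic for a given seed.
    """
    X = sample[list(variables)].to_numpy(dtype=float)
    y = sample[response].to_numpy(dtype=float)
    if len(y) < 30:
        raise ValueError("need at least 30 rows to tune mtry")
    p = X.shape[1]

    cache = {}

    def oob_mse(m: int) -> float:
        if m not in cache:
            rf = RandomForestRegressor(n_estimators=ntree, max_features=m,
                                       oob_score=True, random_state=seed,
                                       n_jobs=1)
            rf.fit(X, y)
            cache[m] = float(np.mean((y - rf.oob_prediction_) ** 2))
        return cache[m]

    start = default_mtry(p)
    best, best_err = start, oob_mse(start)
    for step in (-1, +1):
        m = start + step
        while 1 <= m <= p:
            err = oob_mse(m)
            improves = err < best_err or (err == best_err and m < best)
            if not improves:
                break
            best, best_err = m, err
            m += step
    return best


@dataclass
class SizeEnsemble:
    """Ten independently subsampled random forests plus their holdouts."""

    models: List[RandomForestRegressor]
    variables: List[str]
    train_idx: List[np.ndarray]
    test_idx: List[np.ndarray]
    X: pd.DataFrame
    y: np.ndarray
    mtry: int
    ntree: int

    @property
    def residuals(self) -> np.ndarray:
        """Pooled holdout residuals (observed - predicted, ha)."""
        out = []
        for model, idx in zip(self.models, self.test_idx):
            pred = model.predict(self.X.iloc[idx].to_numpy())
            out.append(self.y[idx] - pred)
        return np.concatenate(out)

    @property
    def variance_explained(self) -> float:
        """Mean over members of 1 - MSE/Var(y) on the member's holdout."""
        scores = []
        for model, idx in zip(self.models, self.test_idx):
            pred = model.predict(self.X.iloc[idx].to_numpy())
            resid = self.y[idx] - pred
            scores.append(1.0 - np.mean(resid ** 2) / np.var(self.y[idx]))
        return float(np.mean(scores))

    @property
    def holdout_correlation(self) -> float:
        """Pearson r between observed and predicted over pooled holdouts."""
        obs, pred = [], []
        for model, idx in zip(self.models, self.test_idx):
            obs.append(self.y[idx])
            pred.append(model.predict(self.X.iloc[idx].to_numpy()))
        return float(np.corrcoef(np.concatenate(obs), np.concatenate(pred))[0, 1])


def fit_ensemble(sample: pd.DataFrame, mtry: Optional[int] = None,
                 n_models: int = 10, ntree: int = 1000,
                 train_frac: float = 2.0 / 3.0,
                 variables: Sequence[str] = SIZE_VARIABLES,
                 response: str = "size_ha",
                 rng: Optional[np.random.Generator] = None) -> SizeEnsemble:
    """Fit ``n_models`` forests on independent random 2/3 subsamples."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = rng or np.random.default_rng(0)
    X = sample[list(variables)].reset_index(drop=True)
    y = sample[response].to_numpy(dtype=float)
    n = len(y)
    n_train = int(round(train_frac * n))
    if mtry is None:
        mtry = default_mtry(len(variables))
    models, train_idx, test_idx = [], [], []
    for _ in range(n_models):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        rf = RandomForestRegressor(
            n_estimators=ntree, max_features=mtry, n_jobs=1,
            random_state=int(rng.integers(0, 2**31)))
        rf.fit(X.iloc[tr].to_numpy(), y[tr])
        models.append(rf)
        train_idx.append(tr)
        test_idx.append(te)
    return SizeEnsemble(models=models, variables=list(variables),
                        train_idx=train_idx, test_idx=test_idx,
                        X=X, y=y, mtry=mtry, ntree=ntree)


def importance(ensemble: SizeEnsemble, n_repeats: int = 5,
               rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Permutation importance (%IncMSE) averaged over the ensemble.

    For each member, each covariate column of its holdout is shuffled
    ``n_repeats`` times and the relative increase in holdout MSE
    (in percent) is recorded; the table reports the average over repeats
    and members, sorted descending.
    """
    rng = rng or np.random.default_rng(0)
    p = len(ensemble.variables)
    inc = np.zeros((len(ensemble.models), p))
    for mi, (model, idx) in enumerate(zip(ensemble.models, ensemble.test_idx)):
        Xte = ensemble.X.iloc[idx].to_numpy().copy()
        yte = ensemble.y[idx]
        base = np.mean((yte - model.predict(Xte)) ** 2)
        for j in range(p):
            deltas = []
            for _ in range(n_repeats):
                Xp = Xte.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                mse = np.mean((yte - model.predict(Xp)) ** 2)
                deltas.append(100.0 * (mse - base) / base)
            inc[mi, j] = np.mean(deltas)
    table = pd.DataFrame({
        "variable": ensemble.variables,
        "pct_inc_mse": inc.mean(axis=0),
    }).sort_values("pct_inc_mse", ascending=False).reset_index(drop=True)
    return table


def predict_size(ensemble: SizeEnsemble, covariates) -> np.ndarray:
    """Ensemble prediction: mean of member predictions, never negative."""
    X = _as_matrix(ensemble, covariates)
    preds = np.mean([m.predict(X) for m in ensemble.models], axis=0)
    return np.maximum(preds, 0.0)


def draw_stochastic_size(ensemble: SizeEnsemble, covariates,
                         rng: np.random.Generator, min_size: float = 0.3,
                         cell_area_ha: Optional[float] = None) -> np.ndarray:
    """Prediction plus a bootstrap draw from the pooled OOB residuals.

    The result is floored at ``min_size`` (the smallest registry size)
    and, when given, at one cell area so the simulator always burns at
    least the ignition cell.
    """
    pred = predict_size(ensemble, covariates)
    resid = ensemble.residuals
    if len(resid):
        pred = pred + rng.choice(resid, size=pred.shape)
    floor = min_size if cell_area_ha is None else max(min_size, cell_area_ha)
    return np.maximum(pred, floor)


def _as_matrix(ensemble: SizeEnsemble, covariates) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        missing = set(ensemble.variables) - set(covariates.columns)
        if missing:
            raise ValueError(f"missing covariates: {sorted(missing)}")
        return covariates[ensemble.variables].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(covariates, dtype=float))
    if arr.shape[1] != len(ensemble.variables):
        raise ValueError("covariate matrix has wrong width")
    return arr
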