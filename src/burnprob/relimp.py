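"""Factor contribution to burn probability: OLS on log BP plus the lmg
(Shapley-over-orderings) decomposition of R-squared.

The response is the natural log of per-cell BP over cells that burned at
least once (log of zero is undefined; a configurable floor of
``1/(2 n_runs)`` can instead retain all burnable cells).  The lmg share
of a regressor is its sequential increase in R-squared averaged over all
orderings of model entry — a Shapley value, computed exactly over the
``2^(p-1)`` subsets with factorial weights rather than by enumerating
``p!`` orderings.  Shares are non-negative for standard OLS fits and sum
to the full-model R-squared; summing shares of related variables gives
group (fuel / topography / human activity) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import LandscapeGrid

#: regressor set for the BP model; distance to settlement is left out as
#: it is highly correlated with distance to road, population density and
#: the remaining human-access signal is carried by dist_road
BP_REGRESSION_VARIABLES: Tuple[str, ...] = (
    "prop_pine", "prop_fir", "prop_broadleaf", "dominant_age",
    "slope", "elevation", "dist_road",
)

#: factor groups used when summing lmg shares
DEFAULT_GROUPING: Dict[str, Tuple[str, ...]] = {
    "fuel": ("prop_pine", "prop_fir", "prop_broadleaf", "dominant_age"),
    "topography": ("slope", "elevation"),
    "human": ("dist_road",),
}


def build_bp_regression(bp: np.ndarray, landscape: LandscapeGrid,
                        variables: Sequence[str] = BP_REGRESSION_VARIABLES,
                        floor: Optional[float] = None,
                        standardize: bool = False):
    """Assemble ``(y, X)`` for the log-BP regression.

    With ``floor=None`` only cells with positive BP enter; otherwise BP
    is floored at ``floor`` and every burnable cell enters.  Raises when
    fewer than ``p + 2`` usable cells remain.
    """
    bp = np.asarray(bp, dtype=float)
    if floor is None:
        mask = (bp > 0) & landscape.burnable
    else:
        bp = np.maximum(bp, floor)
        mask = landscape.burnable
    n = int(mask.sum())
    if n < len(variables) + 2:
        raise ValueError(
            f"only {n} usable cells with positive BP; need at least "
            f"{len(variables) + 2}")
    y = np.log(bp[mask])
    X = pd.DataFrame({v: landscape.layer(v)[mask] for v in variables})
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
    return y, X


@dataclass
class OLSResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    n: int

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"B": self.params, "SE": self.bse,
                             "Sig": self.pvalues})


def ols_fit(X: pd.DataFrame, y: np.ndarray) -> OLSResult:
    """Least-squares fit with classical standard errors.

    Rank-deficient designs are rejected with the names of the columns
    that are linearly dependent on the preceding ones.
    """
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    A = Xc.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        bad = [Xc.columns[i] for i in range(A.shape[1])
               if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    res = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    return OLSResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                     r_squared=float(res.rsquared), n=len(y))


# ---------------------------------------------------------------------------
# lmg decomposition

def _subset_r2_all(X: np.ndarray, y: np.ndarray) -> Dict[int, float]:
    """R-squared of every subset of regressors, keyed by bitmask.

    Uses the cross-moment matrices of centered data; singular submodels
    fall back to a minimum-norm (pseudoinverse) solution.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Sxx = Xc.T @ Xc
    Sxy = Xc.T @ yc
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("response has zero variance")
    r2 = {0: 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            idx = list(subset)
            key = sum(1 << j for j in idx)
            A = Sxx[np.ix_(idx, idx)]
            b = Sxy[idx]
            try:
                coef = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                coef = np.linalg.lstsq(A, b, rcond=None)[0]
            r2[key] = float(np.clip(b @ coef / syy, 0.0, 1.0))
    return r2


def lmg(X: pd.DataFrame, y: np.ndarray, exact_max_p: int = 15,
        n_permutations: int = 2000,
        rng: Optional[np.random.Generator] = None) -> pd.Series:
    """Per-variable lmg shares of the full-model R-squared.

    Exact mode (p <= ``exact_max_p``) averages each variable's sequential
    R-squared gain over all orderings via the subset identity

        share_j = sum_{S not containing j} w(|S|) [R2(S+j) - R2(S)],
        w(s) = s! (p-1-s)! / p!

    For wider designs a sampled-permutation average is used instead.
    """
    cols = list(X.columns)
    p = len(cols)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    if p <= exact_max_p:
        r2 = _subset_r2_all(Xa, ya)
        shares = np.zeros(p)
        weights = {s: factorial(s) * factorial(p - 1 - s) / factorial(p)
                   for s in range(p)}
        for j in range(p):
            bit = 1 << j
            total = 0.0
            for key, val in r2.items():
                if key & bit:
                    continue
                s = bin(key).count("1")
                total += weights[s] * (r2[key | bit] - val)
            shares[j] = total
        return pd.Series(shares, index=cols)
    rng = rng or np.random.default_rng(0)
    shares = np.zeros(p)
    for _ in range(n_permutations):
        order = rng.permutation(p)
        prev = 0.0
        chosen: List[int] = []
        for j in order:
            chosen.append(j)
            idx = sorted(chosen)
            Xc = Xa[:, idx] - Xa[:, idx].mean(axis=0)
            yc = ya - ya.mean()
            coef = np.linalg.lstsq(Xc, yc, rcond=None)[0]
            cur = float(1.0 - np.sum((yc - Xc @ coef) ** 2) / np.sum(yc ** 2))
            shares[j] += cur - prev
            prev = cur
    return pd.Series(shares / n_permutations, index=cols)


def group_shares(shares: pd.Series,
                 grouping: Mapping[str, Sequence[str]]) -> pd.Series:
    """Sum per-variable lmg shares into factor-group contributions."""
    assigned = [v for members in grouping.values() for v in members]
    missing = [v for v in shares.index if v not in assigned]
    if missing:
        raise ValueError(f"variables in no group: {missing}")
    out = {g: float(sum(shares.get(v, 0.0) for v in members))
           for g, members in grouping.items()}
    return pd.Series(out).sort_values(ascending=False)


@dataclass
class ImportanceResult:
    """Full factor-contribution report for the BP regression."""

    ols: OLSResult
    shares: pd.Series
    groups: pd.Series
    r_squared: float

    @property
    def table(self) -> pd.DataFrame:
        t = self.ols.table.copy()
        t["relative_importance"] = self.shares.reindex(t.index)
        return t


def decompose_bp(bp: np.ndarray, landscape: LandscapeGrid,
                 variables: Sequence[str] = BP_REGRESSION_VARIABLES,
                 grouping: Mapping[str, Sequence[str]] = None,
                 floor: Optional[float] = None) -> ImportanceResult:
    """End-to-end: build the log-BP regression, fit OLS, decompose R2."""
    grouping = grouping or DEFAULT_GROUPING
    y, X = build_bp_regression(bp, landscape, variables=variables, floor=floor)
    fit = ols_fit(X, y)
    shares = lmg(X, y)
    groups = group_shares(shares, grouping)
    return ImportanceResult(ols=fit, shares=shares, groups=groups,
                            r_squared=fit.r_squared)
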