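"""Variance attribution: multiple linear regression plus Johnson relative weights.

Why does a temperature-and-greenness model work for some biomes and not
others?  One diagnostic is to regress observed GPP on the candidate drivers
— greenness (EVI), land surface temperature (LST), precipitation (PRC) and
shortwave radiation (RAD) — and split the explained variance among them.
Ordinary regression coefficients are hard to read under correlated
predictors, so the split uses Johnson's relative weight analysis (RWA):

1. standardize y and the predictor columns;
2. eigendecompose the predictor correlation matrix R_XX = QΛQᵀ;
3. form the orthogonal counterpart Z = X·QΛ^{−1/2}Qᵀ — the orthogonal
   matrix closest to X in the least-squares sense; the X–Z correlation
   (loading) matrix is Λ* = QΛ^{1/2}Qᵀ;
4. regress standardized y on Z to get β (since Z is orthonormal, β is just
   the vector of y–Z correlations);
5. the raw weight of predictor j is ε_j = Σ_k (Λ*_jk)² β_k².

The ε_j are non-negative and sum exactly to the full-model R², so
``pct_weights = ε_j / R² × 100`` are shares of explained variance.  For
orthogonal predictors ε_j reduces to the squared zero-order correlation
r²(x_j, y).  Statistical significance of each driver is quoted from the
usual MLR t-tests, not from the weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluate import TaylorStats, taylor_stats
from .tg_model import SiteMonthlySeries

__all__ = [
    "PREDICTORS",
    "RWAResult",
    "AttributionResult",
    "CollinearityError",
    "NoDataError",
    "mlr_fit",
    "relative_weights",
    "attribute_pft",
    "rwa_frame",
]

log = logging.getLogger(__name__)

#: Predictor order used throughout the attribution stage.
PREDICTORS = ("EVI", "LST", "PRC", "RAD")


class CollinearityError(ValueError):
    """Predictor matrix is (numerically) rank deficient."""


class NoDataError(ValueError):
    """Too few pooled months for a stable regression."""


@dataclass
class MLRFit:
    names: tuple[str, ...]
    coefficients: np.ndarray   # standardized slopes
    p_values: np.ndarray
    r_squared: float
    n: int


@dataclass
class RWAResult:
    """Relative-weight decomposition of the MLR's explained variance."""

    predictors: tuple[str, ...]
    raw_weights: np.ndarray     # ε_j, sums to R²
    pct_weights: np.ndarray     # ε_j / R² × 100
    r_squared: float
    mlr_coefficients: np.ndarray
    mlr_p_values: np.ndarray
    n: int


@dataclass
class AttributionResult:
    pft: str
    evi_only_r2: float
    rwa: RWAResult
    mlr_taylor: TaylorStats
    n: int


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = list(np.nonzero(sd == 0)[0])
        raise CollinearityError(f"constant predictor column(s) at index {zero}")
    return (a - a.mean(axis=0)) / sd


def _check_rank(x: np.ndarray, names) -> None:
    corr = np.corrcoef(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < 1e-10:
        # name the most entangled pair for the error message
        off = np.abs(corr - np.eye(len(corr)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise CollinearityError(
            f"predictors are collinear (e.g. {names[i]} vs {names[j]}, "
            f"|r|={off[i, j]:.6f})")


def mlr_fit(X, y, names: tuple[str, ...] | None = None) -> MLRFit:
    """OLS of standardized y on standardized X with the usual t-test p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D table")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 rows, got n={n}, p={p}")
    names = tuple(names) if names else tuple(f"x{i}" for i in range(p))
    xs = _standardize(X)
    _check_rank(xs, names)
    ys = (y - y.mean()) / y.std(ddof=1)
    fit = sm.OLS(ys, sm.add_constant(xs)).fit()
    return MLRFit(
        names=names,
        coefficients=np.asarray(fit.params[1:], dtype=float),
        p_values=np.asarray(fit.pvalues[1:], dtype=float),
        r_squared=float(fit.rsquared),
        n=n,
    )


def relative_weights(X, y, names: tuple[str, ...] | None = None) -> RWAResult:
    """Johnson's relative weights ε_j of each predictor, with Σ ε_j = R²."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    fit = mlr_fit(X, y, names)
    xs = _standardize(X)
    ys = (y - y.mean()) / y.std(ddof=1)
    n = len(ys)
    rxx = (xs.T @ xs) / (n - 1)
    lam, q = np.linalg.eigh(rxx)
    if lam.min() < 1e-10:
        raise CollinearityError("predictor correlation matrix is not positive definite")
    lam_star = q @ np.diag(np.sqrt(lam)) @ q.T          # X–Z loading matrix
    z = xs @ q @ np.diag(1.0 / np.sqrt(lam)) @ q.T       # orthogonal counterpart
    beta = (z.T @ ys) / (n - 1)                          # y–Z correlations
    eps = (lam_star ** 2) @ (beta ** 2)
    r2 = fit.r_squared
    return RWAResult(
        predictors=fit.names,
        raw_weights=eps,
        pct_weights=100.0 * eps / r2 if r2 > 0 else np.full_like(eps, np.nan),
        r_squared=r2,
        mlr_coefficients=fit.coefficients,
        mlr_p_values=fit.p_values,
        n=n,
    )


def attribute_pft(series: list[SiteMonthlySeries] | SiteMonthlySeries,
                  min_months: int = 30) -> AttributionResult:
    """Per-PFT attribution: EVI-only R², 4-predictor relative weights, MLR skill.

    Pools unmasked months with complete (gpp, evi, lst, prc, rad) rows across
    all sites of the PFT.  The Taylor statistics of the full-MLR prediction
    allow a skill comparison against the TG model itself.
    """
    if isinstance(series, SiteMonthlySeries):
        series = [series]
    frames = []
    for s in series:
        d = s.valid_rows()
        ok = np.isfinite(d["prc"]) & np.isfinite(d["rad"])
        frames.append(d.loc[ok])
    pooled = pd.concat(frames) if frames else pd.DataFrame()
    if len(pooled) < min_months:
        raise NoDataError(
            f"only {len(pooled)} pooled months; need at least {min_months}")
    y = pooled["gpp"].to_numpy(float)
    X = pooled[["evi", "lst", "prc", "rad"]].to_numpy(float)
    # (a) single-predictor R² for greenness alone
    evi_fit = sm.OLS(y, sm.add_constant(X[:, [0]])).fit()
    # (b) full relative-weight decomposition
    rwa = relative_weights(X, y, PREDICTORS)
    # (c) skill of the raw-scale MLR prediction for comparison with TG
    full_fit = sm.OLS(y, sm.add_constant(X)).fit()
    stats = taylor_stats(y, np.asarray(full_fit.fittedvalues))
    pft = series[0].pft
    log.info("attribute pft=%s n=%d R2=%.3f evi_only=%.3f",
             pft, len(pooled), rwa.r_squared, evi_fit.rsquared)
    return AttributionResult(pft=pft, evi_only_r2=float(evi_fit.rsquared),
                             rwa=rwa, mlr_taylor=stats, n=len(pooled))


def rwa_frame(result: RWAResult, pft: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "predictor": result.predictors,
        "raw_weight": result.raw_weights,
        "pct_weight": result.pct_weights,
        "mlr_coef": result.mlr_coefficients,
        "p_value": result.mlr_p_values,
        "r_squared": result.r_squared,
        "n": result.n,
    })
    if pft is not None:
        df.insert(0, "pft", pft)
    return df
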