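"""Repeatability, species ANOVA, residualization and partial correlation.

Repeatability (intraclass correlation, tau) uses the one-way consistency
form computed from the between- and within-group mean squares of a balanced
one-way ANOVA: tau = (MSB - MSW) / (MSB + (k-1) MSW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "AnovaResult",
    "icc",
    "anova_species",
    "residualize",
    "partial_pearson",
]


@dataclass
class IccResult:
    tau: float
    df_between: int
    df_within: int
    F: float
    p: float


def icc(measurements: np.ndarray) -> IccResult:
    """Intraclass correlation from a balanced g x k repeated-measures array.

    Rows are groups (specimens / sample points), columns the k repeated
    measurements.  One-way ANOVA mean squares give
    tau = (MSB - MSW) / (MSB + (k-1) MSW) and F = MSB / MSW.
    """
    M = np.asarray(measurements, dtype=float)
    if M.ndim != 2:
        raise ValueError("measurements must be a 2-D (groups x repeats) array")
    g, k = M.shape
    if g < 2 or k < 2:
        raise ValueError("need at least 2 groups and 2 repeats")
    if np.any(np.isnan(M)):
        raise ValueError("unbalanced design: missing measurements")
    grand = M.mean()
    group_means = M.mean(axis=1)
    ssb = k * np.sum((group_means - grand) ** 2)
    ssw = np.sum((M - group_means[:, None]) ** 2)
    df_b, df_w = g - 1, g * (k - 1)
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        return IccResult(tau=1.0, df_between=df_b, df_within=df_w, F=np.inf, p=0.0)
    F = msb / msw
    tau = (msb - msw) / (msb + (k - 1) * msw)
    p = float(stats.f.sf(F, df_b, df_w))
    return IccResult(tau=float(tau), df_between=df_b, df_within=df_w, F=float(F), p=p)


@dataclass
class AnovaResult:
    F: float
    df_effect: int
    df_resid: int
    p: float


def _design_from_factors(factors: pd.DataFrame, n: int) -> np.ndarray:
    blocks = [np.ones((n, 1))]
    for col in factors.columns:
        dummies = pd.get_dummies(factors[col], drop_first=True).to_numpy(float)
        blocks.append(dummies)
    return np.hstack(blocks)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def anova_species(
    trait: np.ndarray,
    species: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> AnovaResult:
    """Sequential (Type-I) F test for a species effect, covariates entered first.

    Fits trait ~ covariates + species and compares residual sums of squares
    of the nested models: F = (dRSS/ddf) / (RSS_full/df_resid).
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    species = pd.Series(species).reset_index(drop=True)
    levels = species.nunique()
    if levels < 2:
        raise ValueError("need at least 2 species")
    cov = (
        covariates.reset_index(drop=True)
        if covariates is not None
        else pd.DataFrame(index=range(n))
    )
    X0 = _design_from_factors(cov, n)
    species_dummies = pd.get_dummies(species, drop_first=True).to_numpy(float)
    X1 = np.hstack([X0, species_dummies])
    rss0, rank0 = _rss(y, X0)
    rss1, rank1 = _rss(y, X1)
    df_effect = rank1 - rank0
    if df_effect < levels - 1:
        raise ValueError("rank-deficient design: species aliased with covariates")
    df_resid = n - rank1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss1 / df_resid
    F = 0.0 if mse == 0 else ((rss0 - rss1) / df_effect) / mse
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_effect, df_resid)) if F > 0 else 1.0
    return AnovaResult(F=float(F), df_effect=df_effect, df_resid=df_resid, p=p)


def residualize(y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on X with an intercept (X may be empty/None).

    Aliased (rank-deficient) columns are handled by the least-squares
    pseudo-inverse; a warning is emitted when rank < columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cols = [np.ones((n, 1))]
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.size:
            cols.append(X[:, None] if X.ndim == 1 else X)
    M = np.hstack(cols)
    if n <= M.shape[1]:
        raise ValueError("too few observations for the predictor block")
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        warnings.warn("rank-deficient predictor block; aliased columns dropped")
    return y - M @ beta


def partial_pearson(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates Z.

    Correlates the OLS residuals of x|Z and y|Z; the p-value uses
    t = r sqrt((n - 2 - q) / (1 - r^2)) with q the number of covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    q = 0 if Z is None or np.size(Z) == 0 else (1 if np.ndim(Z) == 1 else np.shape(Z)[1])
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    df = n - 2 - q
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df / (1 - r_clamped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p
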