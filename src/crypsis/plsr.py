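"""Partial least squares regression with Q² selection and bootstrap inference.

PLSR projects collinear predictors onto latent components that maximise
covariance with the response block; with several responses (multi-response
PLS2) a synthetic response — a linear combination of the original traits —
is predicted.  Components are retained by Q² cross-validation; predictor
importance is the variance-weighted squared weight, and coefficient
uncertainty comes from case-resampling bootstrap.

The module follows a Model/Results design: :class:`PLSRegression` is built
from data and ``fit()`` returns a :class:`PLSResults` carrying estimates,
importance shares, Q² diagnostics and bootstrap standard errors, with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSRFit",
    "BootstrapResult",
    "DesignMatrix",
    "PLSRegression",
    "PLSResults",
    "fit_plsr",
    "cross_validate_q2",
    "variable_importance",
    "bootstrap_coefficients",
    "encode_design",
]

Q2_THRESHOLD = 0.0975  # classical component-retention rule
_NIPALS_TOL = 1e-10
_NIPALS_MAXITER = 500


@dataclass
class PLSRFit:
    """Raw NIPALS decomposition of standardized X (n×p) and Y (n×q).

    W: predictor weights (p×A, unit columns); T: scores (n×A, orthogonal);
    P: X loadings (p×A); C: response weights (q×A); beta: p×q coefficients
    on the standardized scale; explained_Y_variance: percent per component.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    C: np.ndarray
    beta: np.ndarray
    explained_Y_variance: np.ndarray
    A: int

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_Y_variance)

    def beta_truncated(self, a: int) -> np.ndarray:
        """Coefficients using only the first ``a`` components."""
        W, P, C = self.W[:, :a], self.P[:, :a], self.C[:, :a]
        return W @ np.linalg.solve(P.T @ W, C.T)


def fit_plsr(X: np.ndarray, Y: np.ndarray, A: int) -> PLSRFit:
    """NIPALS PLS2 on standardized X and Y with A components.

    X is deflated by each component's loading; Y by the component's
    response weight.  beta is recovered as W (PᵀW)⁻¹ Cᵀ.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    rank = np.linalg.matrix_rank(X)
    if A > rank:
        raise ValueError(f"A={A} exceeds rank(X)={rank}")
    if n <= A:
        raise ValueError("need more observations than components")
    ssy0 = float(np.sum(Y**2))
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    C = np.zeros((q, A))
    explained = np.zeros(A)
    Xa, Ya = X.copy(), Y.copy()
    for a in range(A):
        ssy_before = float(np.sum(Ya**2))
        u = Ya[:, int(np.argmax(np.sum(Ya**2, axis=0)))]
        t_old = np.zeros(n)
        converged = False
        for _ in range(_NIPALS_MAXITER):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("X deflated to zero: too many components")
            w /= nw
            t = Xa @ w
            tt = float(t @ t)
            c = Ya.T @ t / tt
            if q == 1:
                converged = True
                break
            u = Ya @ c / float(c @ c)
            if np.linalg.norm(t - t_old) / max(np.linalg.norm(t), 1e-30) < _NIPALS_TOL:
                converged = True
                break
            t_old = t
        if not converged:
            # near-tied singular values stall the power iteration; take its
            # exact fixed point (dominant singular pair of Xa'Ya) directly
            U, _, _ = np.linalg.svd(Xa.T @ Ya, full_matrices=False)
            w = U[:, 0]
            nz = np.flatnonzero(np.abs(w) > 1e-12)
            if nz.size and w[nz[0]] < 0:
                w = -w
            t = Xa @ w
            tt = float(t @ t)
            c = Ya.T @ t / tt
        p_a = Xa.T @ t / tt
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_a, c
        explained[a] = 100.0 * (ssy_before - float(np.sum(Ya**2))) / ssy0
    beta = W @ np.linalg.solve(P.T @ W, C.T)
    return PLSRFit(W=W, T=T, P=P, C=C, beta=beta, explained_Y_variance=explained, A=A)


def _fold_assignments(
    n: int, folds: int, rng: np.random.Generator, stratify: np.ndarray | None
) -> np.ndarray:
    assign = np.empty(n, dtype=int)
    if stratify is None:
        perm = rng.permutation(n)
        for f in range(folds):
            assign[perm[f::folds]] = f
    else:
        stratify = np.asarray(stratify)
        for level in pd.unique(stratify):
            idx = np.flatnonzero(stratify == level)
            perm = idx[rng.permutation(idx.size)]
            offset = rng.integers(folds)
            for k, i in enumerate(perm):
                assign[i] = (k + offset) % folds
    return assign


def cross_validate_q2(
    X: np.ndarray,
    Y: np.ndarray,
    A_max: int,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    threshold: float = Q2_THRESHOLD,
    stratify: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Per-component Q² from k-fold cross-validation and the selected A.

    Q²(a) = 1 − PRESS(a)/RSS(a−1): held-out prediction error of the
    a-component model against the residual sum of squares of the full-data
    (a−1)-component model (RSS(0) = total SS).  Components are retained
    while Q²(a) ≥ ``threshold``; the selected A is the last retained index
    (0 when the first component already fails).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if not 2 <= folds <= n:
        raise ValueError("folds must lie between 2 and n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A_max = min(A_max, np.linalg.matrix_rank(X))

    for attempt in range(2):
        assign = _fold_assignments(n, folds, rng, stratify)
        ok = True
        for f in range(folds):
            train = assign != f
            if train.sum() <= A_max or np.any(np.ptp(Y[train], axis=0) == 0):
                ok = False
                break
        if ok:
            break
        if attempt == 1:
            raise ValueError("a cross-validation fold has zero response variance")

    press = np.zeros(A_max)
    for f in range(folds):
        train, test = assign != f, assign == f
        a_fit = min(A_max, np.linalg.matrix_rank(X[train]))
        fit = fit_plsr(X[train], Y[train], a_fit)
        for a in range(1, A_max + 1):
            beta = fit.beta_truncated(min(a, a_fit))
            resid = Y[test] - X[test] @ beta
            press[a - 1] += float(np.sum(resid**2))

    full = fit_plsr(X, Y, A_max)
    rss = np.empty(A_max + 1)
    rss[0] = float(np.sum(Y**2))
    for a in range(1, A_max + 1):
        resid = Y - X @ full.beta_truncated(a)
        rss[a] = float(np.sum(resid**2))

    q2 = 1.0 - press / rss[:-1]
    selected = 0
    for a in range(A_max):
        if q2[a] >= threshold:
            selected = a + 1
        else:
            break
    return q2, selected


def variable_importance(fit: PLSRFit, threshold: float = 0.05):
    """Share of explained response variance attributed to each predictor.

    share_j = Σ_a w_ja² · EV_a / Σ_a EV_a, where EV_a is the response
    variance explained by component a; reduces to plain w² at A = 1.
    Flags predictors whose share exceeds ``threshold`` (default 5%).
    """
    ev = fit.explained_Y_variance
    total = ev.sum()
    if total <= 0:
        shares = np.full(fit.W.shape[0], np.nan)
    else:
        shares = (fit.W**2) @ ev / total
    return shares, shares > threshold


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap of PLSR coefficients.

    ``betas`` holds the B replicate coefficient arrays so linear
    combinations of coefficients (e.g. a predictor-block total) can be
    tested after the fact.
    """

    B: int
    se_beta: np.ndarray
    p_beta: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    betas: np.ndarray | None = None

    def linear_combination(
        self, point: np.ndarray, weights: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Estimate, SE and two-sided p for w'beta per response column."""
        if self.betas is None:
            raise ValueError("replicates were not stored")
        est = weights @ point
        draws = np.tensordot(self.betas, weights, axes=([1], [0]))
        se = draws.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf * np.sign(est))
        p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 0.0)
        return est, se, p


def bootstrap_coefficients(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap SEs and p-values for PLSR coefficients at fixed A.

    Rows are resampled with replacement; each replicate is refitted with
    the same number of components.  p-values use the two-sided normal
    approximation of beta/se; percentile confidence intervals are also
    returned.  A replicate whose resampled X collapses below rank A is
    redrawn (at most 10 retries).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    point = fit_plsr(X, Y, A).beta
    betas = np.empty((B,) + point.shape)
    for b in range(B):
        for attempt in range(10 + 1):
            idx = rng.integers(n, size=n)
            Xb, Yb = X[idx], Y[idx]
            if np.linalg.matrix_rank(Xb) >= A:
                break
        else:
            raise RuntimeError("bootstrap replicate rank-deficient after 10 retries")
        betas[b] = fit_plsr(Xb, Yb, A).beta
    se = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, point / se, np.inf * np.sign(point))
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 0.0)
    alpha = 1 - ci_level
    lo = np.quantile(betas, alpha / 2, axis=0)
    hi = np.quantile(betas, 1 - alpha / 2, axis=0)
    return BootstrapResult(
        B=B, se_beta=se, p_beta=p, ci_lower=lo, ci_upper=hi, betas=betas
    )


@dataclass
class DesignMatrix:
    """Standardized predictor matrix with recoverable scaling constants.

    Continuous columns flagged for log transform are log10-ed before
    z-scoring; factors are indicator-coded with the first level dropped.
    ``groups`` maps each column to a predictor block (habitat / geography /
    origin / phylogeny) for variance partitioning.
    """

    column_names: list[str]
    X: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    groups: list[str] = field(default_factory=list)

    def raw(self) -> np.ndarray:
        """Undo the standardization (still on the log scale where logged)."""
        return self.X * self.scale + self.center


def _standardize_col(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = v.mean(), v.std(ddof=1)
    if s == 0:
        raise ValueError("zero-variance column")
    return (v - m) / s, m, s


def encode_design(
    specimens: pd.DataFrame,
    habitat: pd.DataFrame,
    ev_scores: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Build the standardized predictor matrix of the colour-matching model.

    Blocks, in fixed order: habitat colours (log10 + z), latitude and
    longitude (z), collection affiliation indicators, field-collected
    indicator, then any phylogenetic eigenvector scores (z).  All blocks
    must be row-aligned on the specimen table.
    """
    import warnings

    n = len(specimens)
    if len(habitat) != n or (ev_scores is not None and len(ev_scores) != n):
        raise ValueError("blocks are not aligned with the specimen table")
    for df, label in ((specimens, "specimens"), (habitat, "habitat")):
        if df.isna().any().any():
            bad = specimens.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in {label} block at rows {bad}")

    names: list[str] = []
    cols: list[np.ndarray] = []
    centers: list[float] = []
    scales: list[float] = []
    groups: list[str] = []

    for c in habitat.columns:
        v = habitat[c].to_numpy(float)
        if np.any(v <= 0):
            raise ValueError(f"non-positive habitat colour in column {c!r}")
        std, m, s = _standardize_col(np.log10(v))
        names.append(f"log10_{c}_habitat")
        cols.append(std)
        centers.append(m)
        scales.append(s)
        groups.append("habitat")

    for c in ("latitude", "longitude"):
        std, m, s = _standardize_col(specimens[c].to_numpy(float))
        names.append(c)
        cols.append(std)
        centers.append(m)
        scales.append(s)
        groups.append("geography")

    for factor, grp in (("collection", "origin"), ("origin", "origin")):
        if factor not in specimens.columns:
            continue
        levels = pd.unique(specimens[factor])
        if len(levels) < 2:
            warnings.warn(f"factor {factor!r} has a single level; dropped")
            continue
        dummies = pd.get_dummies(specimens[factor], prefix=factor, drop_first=True)
        for c in dummies.columns:
            names.append(c)
            cols.append(dummies[c].to_numpy(float))
            centers.append(0.0)
            scales.append(1.0)
            groups.append(grp)

    if ev_scores is not None:
        for c in ev_scores.columns:
            std, m, s = _standardize_col(ev_scores[c].to_numpy(float))
            names.append(str(c))
            cols.append(std)
            centers.append(m)
            scales.append(s)
            groups.append("phylogeny")

    return DesignMatrix(
        column_names=names,
        X=np.column_stack(cols),
        center=np.array(centers),
        scale=np.array(scales),
        groups=groups,
    )


class PLSRegression:
    """Partial least squares regression model.

    Parameters
    ----------
    Y : response block, n×q (fur colour traits); standardized internally
        unless ``standardize=False``.
    X : predictor block, n×p, or a :class:`DesignMatrix` (already
        standardized).
    """

    def __init__(
        self,
        Y,
        X,
        y_names: list[str] | None = None,
        x_names: list[str] | None = None,
        standardize: bool = True,
    ):
        if isinstance(X, DesignMatrix):
            self.design: DesignMatrix | None = X
            self.X = X.X
            self.x_names = list(X.column_names)
        else:
            self.design = None
            self.X = np.asarray(X, float)
            if standardize:
                self.X = (self.X - self.X.mean(0)) / self.X.std(0, ddof=1)
            self.x_names = x_names or [f"x{j}" for j in range(self.X.shape[1])]
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if standardize:
            Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        self.Y = Y
        self.y_names = y_names or [f"y{j}" for j in range(Y.shape[1])]
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, y_cols: list[str], x_cols: list[str], **kw
    ) -> "PLSRegression":
        return cls(
            data[y_cols].to_numpy(float),
            data[x_cols].to_numpy(float),
            y_names=y_cols,
            x_names=x_cols,
            **kw,
        )

    def fit(
        self,
        n_components: int | None = None,
        select: bool = True,
        folds: int = 10,
        seed: int | np.random.Generator = 0,
        q2_threshold: float = Q2_THRESHOLD,
        stratify: np.ndarray | None = None,
    ) -> "PLSResults":
        """Fit the model; with ``select=True`` the component count is chosen
        by Q² cross-validation (``n_components`` then caps the search)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rank = np.linalg.matrix_rank(self.X)
        a_max = min(n_components or rank, rank)
        q2 = np.array([])
        if select:
            q2, a_sel = cross_validate_q2(
                self.X, self.Y, a_max, folds=folds, seed=rng,
                threshold=q2_threshold, stratify=stratify,
            )
        else:
            a_sel = a_max
        fit = None if a_sel == 0 else fit_plsr(self.X, self.Y, a_sel)
        return PLSResults(self, fit, q2, a_sel)


class PLSResults:
    """Fitted PLSR results: coefficients, importance, Q², bootstrap."""

    def __init__(
        self,
        model: PLSRegression,
        fit: PLSRFit | None,
        q2: np.ndarray,
        n_components: int,
    ):
        self.model = model
        self.fit_ = fit
        self.q2 = q2
        self.n_components = n_components
        self._boot: BootstrapResult | None = None

    @property
    def significant(self) -> bool:
        """Whether any component passed the Q² retention rule."""
        return self.n_components > 0

    @property
    def beta(self) -> np.ndarray:
        if self.fit_ is None:
            raise ValueError("no retained component: model has no coefficients")
        return self.fit_.beta

    @property
    def explained_variance(self) -> float:
        """Percent of response variance explained by the retained components."""
        if self.fit_ is None:
            return 0.0
        return float(self.fit_.cumulative_explained[-1])

    def importance(self, threshold: float = 0.05):
        if self.fit_ is None:
            raise ValueError("no retained component")
        return variable_importance(self.fit_, threshold)

    def component_response_correlation(self) -> tuple[float, float]:
        """Pearson correlation between the first component scores and the
        synthetic response (Y projected on its first response weight)."""
        from crypsis.stats_core import partial_pearson

        if self.fit_ is None:
            raise ValueError("no retained component")
        t1 = self.fit_.T[:, 0]
        u1 = self.model.Y @ self.fit_.C[:, 0]
        return partial_pearson(t1, u1, None)

    def bootstrap(
        self, B: int = 1000, seed: int | np.random.Generator = 0
    ) -> BootstrapResult:
        if self.fit_ is None:
            raise ValueError("no retained component")
        self._boot = bootstrap_coefficients(
            self.model.X, self.model.Y, self.fit_.A, B=B, seed=seed
        )
        return self._boot

    def summary(self) -> pd.DataFrame:
        """Per-predictor table: weight W (component 1), beta per response,
        importance share/flag, and bootstrap SE/p when available."""
        if self.fit_ is None:
            return pd.DataFrame(
                {"note": ["no PLSR component passed the Q² retention rule"]}
            )
        shares, flags = self.importance()
        tbl = pd.DataFrame(
            {
                "predictor": self.model.x_names,
                "W1": self.fit_.W[:, 0],
                "importance_share": shares,
                "important": flags,
            }
        )
        for j, yn in enumerate(self.model.y_names):
            tbl[f"beta[{yn}]"] = self.fit_.beta[:, j]
            if self._boot is not None:
                tbl[f"se[{yn}]"] = self._boot.se_beta[:, j]
                tbl[f"p[{yn}]"] = self._boot.p_beta[:, j]
        return tbl
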