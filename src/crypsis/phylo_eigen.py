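"""Phylogenetic eigenvector regression (PVR) and phylogenetic signal.

Decomposes a patristic distance matrix into orthogonal eigenvectors that
summarise phylogenetic relatedness, selects the vectors that absorb trait
autocorrelation (Moran's I), and measures phylogenetic signal with
signal-representation (PSR) curves: sequential R-squared against cumulative
relative eigenvalues.  The 1:1 line of a PSR curve corresponds to Brownian
motion; negative deviations indicate that close relatives are less similar
than Brownian motion predicts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PatristicMatrix",
    "EigenBasis",
    "MoranResult",
    "PSRCurve",
    "parse_newick",
    "patristic_distances",
    "pvr_eigenvectors",
    "phylo_weight_matrix",
    "morans_i",
    "select_eigenvectors",
    "psr_curve",
    "simulate_bm",
    "assign_species_scores",
]


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Tip labels must be unique and every edge must carry a non-negative
    branch length.
    """

    tree: dendropy.Tree
    taxa: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.taxa = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(self.taxa)) != len(self.taxa):
            raise NewickError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise NewickError(
                    "missing branch length on edge leading to "
                    f"{_node_label(edge.head_node)!r}"
                )
            if edge.length < 0:
                raise NewickError(
                    f"negative branch length {edge.length} on edge leading to "
                    f"{_node_label(edge.head_node)!r}"
                )

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def depth_of(self, taxon: str) -> float:
        """Root-to-tip path length for one tip."""
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == taxon:
                return leaf.distance_from_root()
        raise KeyError(taxon)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths mandatory) into a PhyloTree.

    Raises
    ------
    NewickError
        On syntax errors (with character position where dendropy reports
        one) or when any edge lacks a branch length.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = getattr(exc, "col_num", None)
        at = f" at character {pos}" if pos is not None else ""
        raise NewickError(f"malformed Newick{at}: {exc}") from exc
    return PhyloTree(tree)


@dataclass
class PatristicMatrix:
    """Symmetric matrix of tip-to-tip path lengths along the tree."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("patristic matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("patristic matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.taxa)


def patristic_distances(tree: PhyloTree) -> PatristicMatrix:
    """Tip-to-tip path-length (patristic) distances."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = tree.taxa
    taxon_by_label = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxon_by_label[taxa[i]], taxon_by_label[taxa[j]]
            )
    return PatristicMatrix(taxa, d)


@dataclass
class EigenBasis:
    """Phylogenetic eigenvectors of the double-centered squared-distance matrix.

    Columns are unit-norm, mutually orthogonal, ordered by descending
    (strictly positive) eigenvalue, with the sign convention that each
    column's first nonzero entry is positive.
    """

    taxa: list[str]
    vectors: np.ndarray
    eigenvalues: np.ndarray
    n_discarded_negative: int = 0

    @property
    def m(self) -> int:
        return self.vectors.shape[1]

    def cumulative_eigenvalue_fraction(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / self.eigenvalues.sum()


def pvr_eigenvectors(
    D: PatristicMatrix, eps: float = 1e-10, dist_transform: str = "sqrt"
) -> EigenBasis:
    """Eigendecompose the Gower double-centered patristic matrix.

    With the default ``dist_transform="sqrt"`` the distances are
    square-rooted before principal-coordinates centering, i.e.
    G = -1/2 J D J with J = I - 11'/n.  On an ultrametric tree this G
    equals the centered Brownian-motion covariance exactly, which is what
    makes the 1:1 PSR line the Brownian expectation; it also guarantees a
    Euclidean embedding (no negative eigenvalues).  ``dist_transform=
    "none"`` centers the squared distances (plain PCoA of D) instead.
    Eigenvectors with eigenvalue <= eps * max eigenvalue are discarded;
    negative eigenvalues are counted and dropped.
    """
    n = D.n
    if dist_transform == "sqrt":
        d2 = D.d
    elif dist_transform == "none":
        d2 = D.d**2
    else:
        raise ValueError(f"unknown dist_transform {dist_transform!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eps * max(evals.max(), 0.0)
    n_neg = int(np.sum(evals < 0))
    evals, evecs = evals[keep], evecs[:, keep]
    # reproducible sign convention: first entry of non-negligible magnitude positive
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, k] = -col
    return EigenBasis(list(D.taxa), evecs, evals, n_discarded_negative=n_neg)


def phylo_weight_matrix(D: PatristicMatrix, kind: str = "inverse") -> np.ndarray:
    """Row-standardized phylogenetic weight matrix for Moran's I.

    ``inverse``: w_ij = 1/d_ij; ``inverse-squared``: 1/d_ij^2;
    ``binary-nn``: 1 for each taxon's nearest neighbour(s).  Diagonal zero,
    rows scaled to sum to 1.
    """
    d = D.d
    off = ~np.eye(D.n, dtype=bool)
    if np.any(d[off] <= 0):
        raise ValueError("zero patristic distance between distinct taxa")
    if kind == "inverse":
        w = np.where(off, 1.0 / np.where(off, d, 1.0), 0.0)
    elif kind == "inverse-squared":
        w = np.where(off, 1.0 / np.where(off, d, 1.0) ** 2, 0.0)
    elif kind == "binary-nn":
        w = np.zeros_like(d)
        for i in range(D.n):
            row = np.where(off[i], d[i], np.inf)
            w[i, np.isclose(row, row.min())] = 1.0
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class MoranResult:
    """Moran's I with its null moments under the normality assumption."""

    I: float
    expected: float
    variance: float
    p: float


def morans_i(values: np.ndarray, W: np.ndarray) -> MoranResult:
    """Moran's I autocorrelation of ``values`` under weight matrix ``W``.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centered values.
    Expectation -1/(n-1); variance under the normality assumption; two-sided
    p from the normal approximation.
    """
    from scipy import stats

    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance: all values equal")
    S0 = W.sum()
    I = (n / S0) * float(z @ W @ z) / denom
    EI = -1.0 / (n - 1)
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - EI**2
    var = max(var, 0.0)
    if var > 0:
        zscore = (I - EI) / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(zscore))
    else:
        p = 1.0
    return MoranResult(I=I, expected=EI, variance=var, p=float(p))


def _ols_residuals(y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    n = y.size
    cols = [np.ones(n)]
    if X is not None and X.size:
        cols.append(X[:, None] if X.ndim == 1 else X)
    M = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return y - M @ beta


def select_eigenvectors(
    trait: np.ndarray,
    basis: EigenBasis,
    W: np.ndarray,
    threshold: float = 0.06,
) -> tuple[list[int], bool]:
    """Greedy eigenvector selection driven by residual Moran's I.

    Starting from no vectors, residuals of trait on the selected set are
    tested; while residual I >= threshold, the unselected eigenvector whose
    inclusion minimises residual I is added (ties broken by lower column
    index).  Returns (selected column indices in order of inclusion,
    threshold_met flag).  threshold_met is False only when every vector was
    used and residual autocorrelation still meets or exceeds the threshold.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.size != len(basis.taxa):
        raise ValueError("trait length does not match basis taxa")
    selected: list[int] = []
    remaining = list(range(basis.m))

    def residual_I(cols: list[int]) -> float | None:
        X = basis.vectors[:, cols] if cols else None
        resid = _ols_residuals(trait, X)
        if np.allclose(resid, 0, atol=1e-10) or np.var(resid) < 1e-20:
            return None  # perfect fit: no autocorrelation left to reduce
        return morans_i(resid, W).I

    while True:
        cur = residual_I(selected)
        if cur is None or cur < threshold:
            return selected, True
        if not remaining:
            return selected, False
        best_idx, best_I = None, np.inf
        for j in remaining:
            cand = residual_I(selected + [j])
            cand_I = -np.inf if cand is None else cand
            if cand_I < best_I - 1e-15:
                best_idx, best_I = j, cand_I
        selected.append(best_idx)
        remaining.remove(best_idx)


@dataclass
class PSRCurve:
    """Phylogenetic signal-representation curve.

    Sequential R-squared of the trait on the first k eigenvectors against
    the cumulative relative eigenvalue; mean_deviation is the average signed
    gap R²(k) − cumfrac(k) (negative: trait diverges faster among close
    relatives than Brownian motion predicts), area_deviation the signed
    trapezoid area between the curve and the 1:1 line.
    """

    cum_eigenvalue_fraction: np.ndarray
    r_squared: np.ndarray
    mean_deviation: float
    area_deviation: float


def psr_curve(trait: np.ndarray, basis: EigenBasis) -> PSRCurve:
    """Build the PSR curve from sequential nested PVR fits."""
    trait = np.asarray(trait, dtype=float)
    if basis.m < 2:
        raise ValueError("PSR curve needs at least 2 eigenvectors")
    if np.var(trait) == 0:
        raise ValueError("constant trait")
    cumfrac = basis.cumulative_eigenvalue_fraction()
    tss = float(np.sum((trait - trait.mean()) ** 2))
    r2 = np.empty(basis.m)
    for k in range(1, basis.m + 1):
        resid = _ols_residuals(trait, basis.vectors[:, :k])
        r2[k - 1] = 1.0 - float(resid @ resid) / tss
    dev = r2 - cumfrac
    # area between curve and 1:1 line over x = cumfrac, from the origin
    x = np.concatenate([[0.0], cumfrac])
    y = np.concatenate([[0.0], dev])
    area = float(np.trapezoid(y, x))
    return PSRCurve(
        cum_eigenvalue_fraction=cumfrac,
        r_squared=r2,
        mean_deviation=float(dev.mean()),
        area_deviation=area,
    )


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Simulate a trait under Brownian motion along the tree.

    Each branch contributes an independent Gaussian increment with variance
    sigma2 * branch length; returns tip values keyed by taxon label.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    values: dict[int, float] = {id(tree.tree.seed_node): root_value}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            v = root_value
        else:
            parent_v = values[id(node.parent_node)]
            bl = node.edge.length or 0.0
            v = parent_v + rng.normal(0.0, np.sqrt(sigma2 * bl))
            values[id(node)] = v
        if node.is_leaf():
            out[node.taxon.label] = v
    return out


def assign_species_scores(species: "pd.Series", scores: dict[str, float]):
    """Broadcast species-level scores (e.g. eigenvector loadings) to specimens."""
    import pandas as pd

    species = pd.Series(species)
    unknown = sorted(set(species.unique()) - set(scores))
    if unknown:
        raise KeyError(f"species missing from scores: {unknown}")
    return species.map(scores).astype(float)
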