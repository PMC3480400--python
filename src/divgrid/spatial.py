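"""Spatial principal components analysis (sPCA).

Ordinary PCA of an allele-frequency matrix maximises variance alone; sPCA
instead eigen-decomposes (1/n) X' L X with L the symmetrised spatial
weighting matrix of a connection network, so each axis maximises the product
of the variance of its scores and their Moran's I spatial autocorrelation.
Positive eigenvalues are global structures (clines, patches); negative ones
are local structures (neighbor dissimilarity). Significance of either tail is
assessed by permuting individuals across locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .grid import GridSpec
from .rasters import DiversityRaster, raster_grid_for_points


@dataclass
class SpatialWeights:
    """Row-normalised binary Delaunay adjacency over sample coordinates."""

    W: np.ndarray        # (n, n), zero diagonal, rows sum to 1
    coords: np.ndarray   # (n, 2) lon/lat

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def symmetrised(self) -> np.ndarray:
        return 0.5 * (self.W + self.W.T)


def delaunay_weights(coords, jitter_seed: int = 0, row_normalize: bool = True) -> SpatialWeights:
    """Connection network from the Delaunay triangulation of the points.

    Exact duplicate coordinates are deterministically jittered by <= 1e-6
    degrees so the triangulation is defined; the stored coordinates keep
    their original values.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("Delaunay network needs at least 3 points")
    pts = coords.copy()
    _, first = np.unique(pts, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(n), first)
    if dup.size:
        rng = np.random.default_rng(jitter_seed)
        pts[dup] += rng.uniform(-1e-6, 1e-6, size=(dup.size, 2))
    tri = Delaunay(pts)
    W = np.zeros((n, n))
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                W[simplex[a], simplex[b]] = 1.0
                W[simplex[b], simplex[a]] = 1.0
    if row_normalize:
        W /= W.sum(axis=1, keepdims=True)
    return SpatialWeights(W=W, coords=coords)


def morans_I(values, weights) -> float:
    """Moran's I = (n / S0) * (z' W z) / (z' z) with z the centered values."""
    W = weights.W if isinstance(weights, SpatialWeights) else np.asarray(weights, float)
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values have no spatial autocorrelation")
    s0 = W.sum()
    return float(len(z) / s0 * (z @ W @ z) / denom)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray   # signed, sorted descending
    vectors: np.ndarray       # (p, n_axes) loadings on centered allele columns
    scores: np.ndarray        # (n, n_axes)
    variance: np.ndarray      # per-axis var of scores (1/n)
    moran: np.ndarray         # per-axis Moran's I of scores
    trace: float


def spca_decompose(X, weights) -> SpcaResult:
    """Eigen-decompose (1/n) X' L X, L = (W + W')/2, of the centered matrix X.

    Each eigenvalue equals the variance of its score vector times its Moran's
    I (exactly, for row-normalised weights where the total weight is n).
    """
    W = weights.W if isinstance(weights, SpatialWeights) else np.asarray(weights, float)
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("matrix has no variance")
    n = Xc.shape[0]
    L = 0.5 * (W + W.T)
    M = Xc.T @ L @ Xc / n
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = Xc @ evecs
    var = (scores ** 2).mean(axis=0)  # scores are column-centered (Xc centered)
    s0 = L.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.einsum("ia,ij,ja->a", scores, L, scores)
        moran = np.where(var > 0, n / s0 * num / (n * var), np.nan)
    return SpcaResult(eigenvalues=evals, vectors=evecs, scores=scores,
                      variance=var, moran=moran, trace=float(np.trace(M)))


def _signed_mass(evals: np.ndarray):
    return float(evals[evals > 0].sum()), float(-evals[evals < 0].sum())


def global_local_test(X, weights, n_perm: int = 99, seed: int = 0):
    """Monte-Carlo test for global and local spatial structure.

    Statistics are the total positive (global) and absolute negative (local)
    eigenvalue mass of the sPCA decomposition; the null redistributes the
    individuals over the observed locations at random. One-sided p-values as
    in the Mantel test. Uses the identity that the non-zero spectrum of
    (1/n) X' L X equals that of (1/n) S U' L U S from the thin SVD
    X = U S V', so permutations only reshuffle rows of U.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    W = weights.W if isinstance(weights, SpatialWeights) else np.asarray(weights, float)
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    n = Xc.shape[0]
    L = 0.5 * (W + W.T)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = S > S.max() * 1e-10
    U, S = U[:, keep], S[keep]

    def stats(perm):
        Up = U[perm]
        M = (S[:, None] * (Up.T @ L @ Up) * S[None, :]) / n
        return _signed_mass(np.linalg.eigvalsh(M))

    g_obs, l_obs = stats(np.arange(n))
    rng = np.random.default_rng(seed)
    g_count = l_count = 0
    for _ in range(n_perm):
        g, l = stats(rng.permutation(n))
        if g >= g_obs - 1e-12:
            g_count += 1
        if l >= l_obs - 1e-12:
            l_count += 1
    return (1 + g_count) / (1 + n_perm), (1 + l_count) / (1 + n_perm)


def spca_score_raster(scores, coords, grid: GridSpec, diameter: float = 1.0,
                      statistic_name: str = "spca_axis1") -> DiversityRaster:
    """Raster of mean sPCA scores per cell over a circular neighborhood.

    Each cell takes the mean score of all individuals within ``diameter/2``
    of its CENTER (note: centered on cells, unlike the tree-centered
    replication used for diversity surfaces); empty cells are nodata.
    """
    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if scores.shape[0] != coords.shape[0]:
        raise ValueError("scores and coords must align")
    raster = raster_grid_for_points(coords, grid, pad=diameter / 2.0,
                                    statistic_name=statistic_name)
    tree = cKDTree(coords)
    centers, cells = raster.cell_centers()
    hits = tree.query_ball_point(centers, r=diameter / 2.0 * (1 + 1e-12))
    for (col, row), idx in zip(cells, hits):
        if idx:
            raster.set_value(col, row, float(scores[idx].mean()))
    return raster
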