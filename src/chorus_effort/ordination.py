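"""Non-metric multidimensional scaling (NMDS) of assemblage dissimilarities.

Kruskal's classic formulation: find a k-dimensional configuration whose
inter-point distances are, as nearly as possible, a monotone function of
the input dissimilarities. Each iteration fits monotone (pool-adjacent-
violators) disparities to the configuration distances in dissimilarity
rank order, then moves the configuration with a Guttman transform toward
those disparities; stress-1

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 )

is tracked and an update is only accepted while it does not increase.
The best of several seeded random starts is returned, centered and
rotated to principal axes (solutions are otherwise free to rotate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .model import IncidenceMatrix


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: np.ndarray  # (n_points, k), centered, principal-axis rotated
    stress: float
    n_restarts: int
    converged: bool


def kruskal_stress(dissimilarity: np.ndarray, coordinates: np.ndarray) -> float:
    """Stress-1 of a configuration against a dissimilarity matrix,
    using monotone-regression disparities (useful for invariance checks)."""
    diss = _validate_square(dissimilarity)
    vec = squareform(diss, checks=False)
    order = np.argsort(vec, kind="stable")
    d = pdist(np.asarray(coordinates, dtype=float))
    return _stress_and_disparities(d, order)[0]


def _validate_square(dissimilarity: np.ndarray) -> np.ndarray:
    diss = np.asarray(dissimilarity, dtype=float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError(f"dissimilarity must be square, got shape {diss.shape}")
    if not np.allclose(diss, diss.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(diss < 0):
        raise ValueError("dissimilarities must be non-negative")
    if not np.allclose(np.diag(diss), 0.0, atol=1e-12):
        raise ValueError("dissimilarity diagonal must be zero")
    return diss


def _stress_and_disparities(d: np.ndarray, order: np.ndarray) -> tuple[float, np.ndarray]:
    """PAV-fit disparities to distances in dissimilarity rank order."""
    dhat = np.empty_like(d)
    fit = isotonic_regression(d[order]).x
    dhat[order] = fit
    denom = float(np.sum(d * d))
    if denom <= 0.0:
        return 0.0, dhat
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom)), dhat


def _guttman_update(X: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    B = -squareform(ratio, checks=False)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def nmds(
    dissimilarity: np.ndarray,
    k: int = 2,
    *,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Best-of-restarts NMDS of a symmetric dissimilarity matrix.

    Parameters mirror the usual community-ecology defaults: ``k=2`` axes,
    20 seeded random starts, convergence on relative stress change below
    ``tol``. Deterministic for a fixed seed.
    """
    diss = _validate_square(dissimilarity)
    n = diss.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    if n < 2:
        raise ValueError("need at least two points")
    vec = squareform(diss, checks=False)
    order = np.argsort(vec, kind="stable")
    scale = float(vec.max()) or 1.0

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, bool] | None = None
    for _ in range(restarts):
        X = rng.uniform(-scale, scale, size=(n, k))
        d = pdist(X)
        stress, dhat = _stress_and_disparities(d, order)
        converged = False
        n_pairs = d.shape[0]
        for _ in range(max_iter):
            # anchor the disparities to a fixed sum of squares before the
            # Guttman step: otherwise poor fits let the configuration drift
            # toward the origin (stress-1 itself is scale-invariant)
            ss = float(np.sum(dhat * dhat))
            target = dhat * np.sqrt(n_pairs / ss) if ss > 0 else dhat
            X_new = _guttman_update(X, d, target)
            d_new = pdist(X_new)
            stress_new, dhat_new = _stress_and_disparities(d_new, order)
            if stress_new > stress:  # no further improvement: local minimum reached
                converged = True
                break
            rel = (stress - stress_new) / stress if stress > 0 else 0.0
            X, d, stress, dhat = X_new, d_new, stress_new, dhat_new
            if rel < tol:
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, X, converged)

    stress, X, converged = best
    X = X - X.mean(axis=0)
    # canonical orientation: rotate to principal axes, fix sign per axis
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):
        col = X[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            X[:, j] = -col
    return OrdinationResult(coordinates=X, stress=stress, n_restarts=restarts, converged=converged)


def assemblage_dissimilarity(matrix: IncidenceMatrix, metric: str = "euclidean") -> np.ndarray:
    """Pairwise distances between the unit rows of a presence/absence
    matrix: ``euclidean`` (the ordination default here) or ``sorensen``
    (the Dice dissimilarity (b+c)/(2a+b+c) on binary rows)."""
    cells = matrix.cells.astype(float)
    if metric == "euclidean":
        return squareform(pdist(cells, metric="euclidean"))
    if metric == "sorensen":
        d = squareform(pdist(matrix.cells.astype(bool), metric="dice"))
        return np.nan_to_num(d, nan=0.0)  # two all-zero rows are identical
    raise ValueError(f"unknown metric {metric!r}; expected 'euclidean' or 'sorensen'")
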