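"""Linear neighborhood similarity: per-entity simplex-constrained QP.

Each entity's feature vector (its row or column of the completed association
matrix) is reconstructed as a convex combination of its K nearest neighbors.
The reconstruction weights solve

    min_w  w' (G + lambda I) w    s.t.  sum(w) = 1,  w >= 0

where G[j, l] = (x_i - x_j) . (x_i - x_l) is the neighborhood Gram matrix of
displacement inner products and lambda is a ridge term that breaks the
degeneracy of coincident neighbors.  The stacked weight vectors form a
row-stochastic, generally asymmetric similarity matrix used as a directed
graph by the downstream predictors.

The QP is solved by an accelerated projected-gradient method (FISTA with
Euclidean projection onto the probability simplex), with a monotone fallback
restart.  For lambda > 0 the objective is strongly convex, so the minimizer
is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import SimilarityMatrix
from .errors import NumericalError, ValidationError

__all__ = [
    "LnsParams",
    "NeighborhoodWeights",
    "neighborhood_gram",
    "project_simplex",
    "solve_neighbor_weights",
    "linear_neighborhood_similarity",
]


@dataclass(frozen=True)
class LnsParams:
    """K: neighborhood size (capped at p-1); lam: ridge regularization weight."""

    K: int = 100
    lam: float = 1.0

    def validate(self) -> "LnsParams":
        if self.K < 1:
            raise ValidationError(f"neighborhood size K must be >= 1, got {self.K}")
        if self.lam < 0:
            raise ValidationError(f"regularization lambda must be >= 0, got {self.lam}")
        return self


@dataclass
class NeighborhoodWeights:
    """Solution of one per-entity QP: indices, simplex weights, objective value."""

    entity_index: int
    neighbor_indices: list[int]
    weights: np.ndarray
    objective: float


def neighborhood_gram(x_i: np.ndarray, X_nbrs: np.ndarray) -> np.ndarray:
    """Gram matrix of displacements: G[j, l] = (x_i - x_j) . (x_i - x_l).

    Symmetric and positive semidefinite by construction.
    """
    D = np.atleast_2d(x_i) - np.atleast_2d(X_nbrs)
    return D @ D.T


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex {w >= 0, sum w = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    ind = np.arange(1, v.size + 1)
    rho = np.nonzero(u * ind > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def solve_neighbor_weights(
    G: np.ndarray,
    lam: float,
    entity_index: int = -1,
    neighbor_indices: list[int] | None = None,
    tol: float = 1e-12,
    max_iter: int = 20000,
) -> NeighborhoodWeights:
    """Minimize w'(G + lam I)w over the probability simplex.

    Uses FISTA with simplex projection; the step size is 1/L with
    L = 2 * lambda_max(G + lam I).  With lam = 0 and singular G the minimizer
    may be non-unique; any feasible optimum is returned.
    """
    K = G.shape[0]
    if G.shape != (K, K):
        raise ValidationError("Gram matrix must be square")
    A = (G + G.T) / 2.0 + lam * np.eye(K)
    if K == 1:
        w = np.ones(1)
        return NeighborhoodWeights(entity_index, list(neighbor_indices or [0]), w, float(A[0, 0]))
    L = 2.0 * max(float(np.linalg.eigvalsh(A)[-1]), 1e-15)
    w = np.full(K, 1.0 / K)
    z = w.copy()
    t = 1.0
    f_prev = float(w @ A @ w)
    for _ in range(max_iter):
        grad = 2.0 * (A @ z)
        w_new = project_simplex(z - grad / L)
        f_new = float(w_new @ A @ w_new)
        if f_new > f_prev:  # monotone restart
            w_new = project_simplex(w - 2.0 * (A @ w) / L)
            f_new = float(w_new @ A @ w_new)
            z = w_new.copy()
            t = 1.0
        else:
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            z = w_new + ((t - 1.0) / t_new) * (w_new - w)
            t = t_new
        delta = np.abs(w_new - w).max()
        w = w_new
        if not np.isfinite(f_new):
            raise NumericalError(f"QP diverged for entity {entity_index}")
        if delta < tol and abs(f_prev - f_new) <= tol * max(1.0, f_prev):
            f_prev = f_new
            break
        f_prev = f_new
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    idx = list(neighbor_indices) if neighbor_indices is not None else list(range(K))
    return NeighborhoodWeights(entity_index, idx, w, float(w @ A @ w))


def _nearest_neighbors(X: np.ndarray, i: int, K: int) -> list[int]:
    """Indices of the K nearest rows to row i (Euclidean), self excluded,
    distance ties broken toward the lower index."""
    d = np.linalg.norm(X - X[i], axis=1)
    order = sorted((j for j in range(X.shape[0]) if j != i), key=lambda j: (d[j], j))
    return order[:K]


def linear_neighborhood_similarity(
    X: np.ndarray,
    params: LnsParams = LnsParams(),
    ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Learn the row-stochastic linear neighborhood similarity from features X.

    Row i holds entity i's reconstruction weights scattered onto its K nearest
    neighbors; all other entries (including the diagonal) are zero.  Tiny
    negative weights from floating point are clipped and the row renormalized.
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    if p < 2:
        raise ValidationError("need at least 2 entities to learn neighborhood similarity")
    K = min(params.K, p - 1)
    S = np.zeros((p, p))
    for i in range(p):
        nbrs = _nearest_neighbors(X, i, K)
        G = neighborhood_gram(X[i], X[nbrs])
        sol = solve_neighbor_weights(G, params.lam, entity_index=i, neighbor_indices=nbrs)
        S[i, nbrs] = sol.weights
    if ids is None:
        ids = [f"e{i}" for i in range(p)]
    return SimilarityMatrix(list(ids), S, kind="linear_neighborhood").validate()
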