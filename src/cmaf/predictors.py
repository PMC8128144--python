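"""The three base predictors over the completed network and learned similarities.

* **Label propagation (LPRIA).**  Scores diffuse over the directed
  linear-neighborhood graph: ``Y_{t+1} = alpha S Y_t + (1 - alpha) Y_0``,
  whose fixed point is ``(1 - alpha)(I - alpha S)^{-1} Y_0``.  Run once over
  drugs and once over diseases; the two sides are averaged.

* **Graph-regularized NMF (NMFRIA).**  ``Y ~ W H'`` with non-negativity,
  Tikhonov penalties and Laplacian smoothness on both factor matrices, fitted
  by multiplicative updates whose objective is non-increasing.

* **Network consistency projection (NCPRIA).**  Cosine-style projection of
  each similarity row onto the corresponding association column (and vice
  versa), normalized by the similarity row/column lengths; bounded in [0, 1]
  by Cauchy-Schwarz since all entries are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core_data import DrugDiseaseNetwork, ScoreMatrix, SimilarityMatrix
from .errors import MatrixValueError, NumericalError, ShapeError, ValidationError

__all__ = [
    "LpParams",
    "NmfParams",
    "FactorPair",
    "label_propagation",
    "lpria_predict",
    "nmf_objective",
    "nmfria_fit",
    "nmfria_predict",
    "ncpria_predict",
]

_EPS = 1e-12  # multiplicative-update denominator floor
_ZERO_FILL = 1e-30  # stand-in for unobserved zeros in the projection step


@dataclass(frozen=True)
class LpParams:
    """alpha: probability of absorbing neighbor labels per step, in (0, 1)."""

    alpha: float = 0.5
    mode: str = "closed_form"  # or "iterative"
    tol: float = 1e-10
    max_iter: int = 10000

    def validate(self) -> "LpParams":
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"label propagation alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("closed_form", "iterative"):
            raise ValidationError(f"unknown label propagation mode {self.mode!r}")
        return self


@dataclass(frozen=True)
class NmfParams:
    """Latent rank k (capped at min(m, n) - 1), Tikhonov weight lam_l, and
    graph-regularization weights lam_r (drugs) / lam_d (diseases)."""

    k: int = 100
    lam_l: float = 2.0
    lam_r: float = 1e-4
    lam_d: float = 1e-4
    max_iter: int = 2000
    rel_tol: float = 1e-6
    seed: int = 0

    def validate(self) -> "NmfParams":
        if self.k < 1:
            raise ValidationError(f"NMF rank k must be >= 1, got {self.k}")
        if min(self.lam_l, self.lam_r, self.lam_d) < 0:
            raise ValidationError("NMF regularization weights must be >= 0")
        if self.max_iter < 1 or self.rel_tol < 0:
            raise ValidationError("NMF iteration controls out of range")
        return self


@dataclass
class FactorPair:
    """Non-negative factors W (m x k), H (n x k) and the objective trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    drug_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)


def _sim_array(S, p: int, what: str) -> np.ndarray:
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if A.shape != (p, p):
        raise ShapeError(f"{what} similarity shape {A.shape} does not match {p} entities")
    return A


# ---------------------------------------------------------------------------
# Label propagation


def label_propagation(S, Y0: np.ndarray, params: LpParams = LpParams()) -> np.ndarray:
    """Propagate the labels Y0 over the row-stochastic graph S.

    Closed form solves ``(I - alpha S) Y = (1 - alpha) Y0``; iterative mode
    repeats the update until the max-abs change drops below ``tol``.  Both
    agree to high precision because the iteration is a contraction for
    alpha < 1.
    """
    params.validate()
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    Y0 = np.asarray(Y0, dtype=float)
    p = A.shape[0]
    if A.shape != (p, p) or Y0.shape[0] != p:
        raise ShapeError(f"similarity {A.shape} incompatible with labels {Y0.shape}")
    if params.mode == "closed_form":
        try:
            out = scipy.linalg.solve(np.eye(p) - params.alpha * A, (1.0 - params.alpha) * Y0)
        except scipy.linalg.LinAlgError as exc:  # cannot occur for row-stochastic S, a < 1
            raise NumericalError("label propagation system is singular") from exc
    else:
        out = Y0.copy()
        for _ in range(params.max_iter):
            nxt = params.alpha * (A @ out) + (1.0 - params.alpha) * Y0
            delta = np.abs(nxt - out).max() if out.size else 0.0
            out = nxt
            if delta < params.tol:
                break
    if not np.all(np.isfinite(out)):
        raise NumericalError("label propagation produced non-finite scores")
    return out


def lpria_predict(
    net_completed: DrugDiseaseNetwork,
    Sr_star: SimilarityMatrix,
    Sd_star: SimilarityMatrix,
    params: LpParams = LpParams(),
) -> ScoreMatrix:
    """Two-sided label propagation: average of the drug-side and disease-side runs."""
    m, n = net_completed.shape
    Sr = _sim_array(Sr_star, m, "drug")
    Sd = _sim_array(Sd_star, n, "disease")
    Yr = label_propagation(Sr, net_completed.Y, params)
    Yd = label_propagation(Sd, net_completed.Y.T, params).T
    R = (Yr + Yd) / 2.0
    R = np.clip(R, 0.0, 1.0)  # trim float dust; mathematically already in [0, 1]
    return ScoreMatrix(
        list(net_completed.drug_ids), list(net_completed.disease_ids), R, source="LPRIA"
    ).validate()


# ---------------------------------------------------------------------------
# Graph-regularized NMF


def _laplacian_parts(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized similarity and its degree vector.

    The learned neighborhood similarity is asymmetric; the Laplacian smoothness
    term Tr(W' L W) is only guaranteed non-negative for symmetric graphs, so
    the graph terms use S_sym = (S + S') / 2 and D = rowsum(S_sym).
    """
    S_sym = (S + S.T) / 2.0
    return S_sym, S_sym.sum(axis=1)


def nmf_objective(
    Y: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    Sr_sym: np.ndarray,
    dr: np.ndarray,
    Sd_sym: np.ndarray,
    dd: np.ndarray,
    params: NmfParams,
) -> float:
    """Penalized squared-error objective evaluated at (W, H)."""
    fit = float(np.linalg.norm(Y - W @ H.T, "fro") ** 2)
    tik = params.lam_l * float((W * W).sum() + (H * H).sum())
    graph_r = params.lam_r * float((dr * (W * W).sum(axis=1)).sum() - (W.T @ Sr_sym @ W).trace())
    graph_d = params.lam_d * float((dd * (H * H).sum(axis=1)).sum() - (H.T @ Sd_sym @ H).trace())
    return fit + tik + graph_r + graph_d


def nmfria_fit(
    net_completed: DrugDiseaseNetwork,
    Sr_star: SimilarityMatrix,
    Sd_star: SimilarityMatrix,
    params: NmfParams = NmfParams(),
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FactorPair:
    """Fit the graph-regularized NMF by multiplicative updates.

    Factors are initialized uniformly on [0, sqrt(mean(Y) / k)] (scale-matched
    so W H' starts near the data's mean) from ``params.seed``, unless an
    explicit ``init`` is given.  Updates stop when the relative objective
    change falls below ``rel_tol`` or after ``max_iter`` sweeps.
    """
    params.validate()
    Y = net_completed.Y
    m, n = Y.shape
    if Y.size and Y.min() < 0:
        raise MatrixValueError("NMF requires a non-negative matrix")
    Sr_sym, dr = _laplacian_parts(_sim_array(Sr_star, m, "drug"))
    Sd_sym, dd = _laplacian_parts(_sim_array(Sd_star, n, "disease"))
    k = max(1, min(params.k, min(m, n) - 1))
    if init is not None:
        W, H = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
        if W.shape[0] != m or H.shape[0] != n or W.shape[1] != H.shape[1]:
            raise ShapeError("initial factors do not match the network dimensions")
    else:
        rng = np.random.default_rng(params.seed)
        scale = float(np.sqrt(max(Y.mean(), 0.0) / k))
        W = rng.uniform(0.0, scale, size=(m, k))
        H = rng.uniform(0.0, scale, size=(n, k))
    trace = [nmf_objective(Y, W, H, Sr_sym, dr, Sd_sym, dd, params)]
    for _ in range(params.max_iter):
        numer = Y @ H + params.lam_r * (Sr_sym @ W)
        denom = W @ (H.T @ H) + params.lam_l * W + params.lam_r * (dr[:, None] * W)
        W = W * numer / np.maximum(denom, _EPS)
        numer = Y.T @ W + params.lam_d * (Sd_sym @ H)
        denom = H @ (W.T @ W) + params.lam_l * H + params.lam_d * (dd[:, None] * H)
        H = H * numer / np.maximum(denom, _EPS)
        W = np.maximum(W, 0.0)
        H = np.maximum(H, 0.0)
        obj = nmf_objective(Y, W, H, Sr_sym, dr, Sd_sym, dd, params)
        if not np.isfinite(obj):
            raise NumericalError("NMF objective became non-finite")
        trace.append(obj)
        if abs(trace[-2] - obj) <= params.rel_tol * max(abs(trace[-2]), _EPS):
            break
    return FactorPair(
        W, H, trace, list(net_completed.drug_ids), list(net_completed.disease_ids)
    )


def nmfria_predict(factors: FactorPair) -> ScoreMatrix:
    """Reconstruct the score matrix W H' (non-negative, may exceed 1)."""
    R = factors.W @ factors.H.T
    return ScoreMatrix(
        list(factors.drug_ids), list(factors.disease_ids), R, source="NMFRIA"
    ).validate()


# ---------------------------------------------------------------------------
# Network consistency projection


def ncpria_predict(
    net_completed: DrugDiseaseNetwork,
    Sr_star: SimilarityMatrix,
    Sd_star: SimilarityMatrix,
) -> ScoreMatrix:
    """Fused drug-space and disease-space consistency projections.

    Exact zeros of Y stand in as 1e-30 so that no profile is the zero vector;
    an unobserved pair then projects onto the similarity structure rather than
    dividing by zero.  The fused score is normalized by the sum of the
    similarity row/column lengths and lies in [0, 1].
    """
    m, n = net_completed.shape
    Sr = _sim_array(Sr_star, m, "drug")
    Sd = _sim_array(Sd_star, n, "disease")
    Y = np.where(net_completed.Y == 0.0, _ZERO_FILL, net_completed.Y)
    col_norm = np.linalg.norm(Y, axis=0)
    row_norm = np.linalg.norm(Y, axis=1)
    ncp_r = (Sr @ Y) / col_norm[None, :]
    ncp_d = (Y @ Sd) / row_norm[:, None]
    denom = np.linalg.norm(Sr, axis=1)[:, None] + np.linalg.norm(Sd, axis=0)[None, :]
    if (denom == 0.0).any():
        i, j = np.argwhere(denom == 0.0)[0]
        raise MatrixValueError(
            f"zero similarity row and column for pair "
            f"({net_completed.drug_ids[i]!r}, {net_completed.disease_ids[j]!r})"
        )
    R = (ncp_r + ncp_d) / denom
    R = np.clip(R, 0.0, 1.0)  # Cauchy-Schwarz bound, up to float dust
    return ScoreMatrix(
        list(net_completed.drug_ids), list(net_completed.disease_ids), R, source="NCPRIA"
    ).validate()
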