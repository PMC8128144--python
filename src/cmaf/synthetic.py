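"""Synthetic drug-disease networks with planted low-rank structure.

The generator emulates the shape of curated repositioning gold standards — a
sparse binary bipartite matrix (hundreds of drugs by hundreds of diseases at
a fraction-of-a-percent to few-percent density) accompanied by two symmetric
similarity matrices in [0, 1] with unit diagonal that are informative about
the association pattern.

Structure is planted through non-negative latent factors over ``r``
therapeutic themes.  Each entity is assigned one dominant theme (drugs of a
class treat diseases of a family), with a per-entity Gamma activity level and
a small uniform cross-theme background, so association probabilities
P proportional to U V' are high and graded inside matching theme blocks and
near zero elsewhere — the block structure characteristic of curated
repositioning gold standards.  P is rescaled so its mean matches the target
density, and similarities are the cosines of the latent loadings plus
symmetric Gaussian noise — correlated with the association pattern exactly
the way fingerprint and phenotype similarities are assumed to be.

Structure and noise use two independent seeded substreams so the noise level
can vary while the planted network stays fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_data import DrugDiseaseNetwork, SimilarityMatrix
from .errors import NumericalError, ValidationError

__all__ = ["SyntheticSpec", "generate", "mask_positives"]

_ACTIVITY_SHAPE = 1.0  # Gamma shape of per-entity activity: exponential, heavy-tailed
_BACKGROUND = 0.05  # cross-theme leakage relative to the dominant theme


@dataclass(frozen=True)
class SyntheticSpec:
    """Problem size, planted rank, target density, similarity noise, seed."""

    m: int = 150
    n: int = 100
    r: int = 6
    density: float = 0.06
    similarity_noise: float = 0.1
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.m < 2 or self.n < 2:
            raise ValidationError("need at least 2 drugs and 2 diseases")
        if not (1 <= self.r <= min(self.m, self.n)):
            raise ValidationError(f"rank r={self.r} must lie in [1, min(m, n)]")
        if not (0.0 < self.density < 1.0):
            raise ValidationError(f"density must lie in (0, 1), got {self.density}")
        if self.similarity_noise < 0:
            raise ValidationError("similarity noise must be >= 0")
        return self


def _latent_factors(p: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """Theme-block loadings: one dominant theme per entity, scaled by a
    Gamma-distributed activity, plus a small uniform cross-theme background."""
    themes = rng.integers(0, r, size=p)
    activity = rng.gamma(_ACTIVITY_SHAPE, 1.0 / _ACTIVITY_SHAPE, size=p)
    U = _BACKGROUND * rng.uniform(size=(p, r))
    U[np.arange(p), themes] += 1.0
    return activity[:, None] * U


def _scale_to_density(B: np.ndarray, density: float) -> np.ndarray | None:
    """Find c such that mean(min(c * B, 1)) == density, by bisection.

    Returns None when the target is unreachable (degenerate factors).
    """
    if B.max() <= 0:
        return None
    lo, hi = 0.0, 1.0
    while np.minimum(hi * B, 1.0).mean() < density:
        hi *= 2.0
        if hi > 1e18:
            return None
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if np.minimum(mid * B, 1.0).mean() < density:
            lo = mid
        else:
            hi = mid
    P = np.minimum(hi * B, 1.0)
    if abs(P.mean() - density) > 1e-6 * density:
        return None
    return P


def _cosine_rows(U: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(U, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    S = (U / norms[:, None]) @ (U / norms[:, None]).T
    return np.clip(S, 0.0, 1.0)


def _noisy_similarity(C: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    p = C.shape[0]
    noise = np.triu(rng.normal(0.0, sigma, size=(p, p)), k=1)
    S = np.clip(C + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(
    spec: SyntheticSpec,
) -> tuple[DrugDiseaseNetwork, SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """Draw a planted network, its two noisy similarities, and the truth P.

    Returns ``(net, S_r, S_d, P)`` where ``Y ~ Bernoulli(P)`` entrywise and
    the similarities are cosine similarities of the latent loadings with
    symmetric Gaussian noise of sd ``similarity_noise``.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    struct_ss, noise_ss = root.spawn(2)
    noise_rng = np.random.default_rng(noise_ss)
    for attempt_ss in struct_ss.spawn(10):
        rng = np.random.default_rng(attempt_ss)
        U = _latent_factors(spec.m, spec.r, rng)
        V = _latent_factors(spec.n, spec.r, rng)
        P = _scale_to_density(U @ V.T, spec.density)
        if P is not None:
            break
    else:
        raise NumericalError("target density unreachable after 10 factor draws")
    Y = (rng.uniform(size=P.shape) < P).astype(float)
    drug_ids = [f"DR{i:04d}" for i in range(spec.m)]
    disease_ids = [f"DS{j:04d}" for j in range(spec.n)]
    net = DrugDiseaseNetwork(drug_ids, disease_ids, Y).validate(binary=True)
    S_r = SimilarityMatrix(
        drug_ids, _noisy_similarity(_cosine_rows(U), spec.similarity_noise, noise_rng), "input"
    ).validate()
    S_d = SimilarityMatrix(
        disease_ids, _noisy_similarity(_cosine_rows(V), spec.similarity_noise, noise_rng), "input"
    ).validate()
    return net, S_r, S_d, P


def mask_positives(
    net: DrugDiseaseNetwork,
    fraction: float,
    seed: int = 0,
) -> tuple[DrugDiseaseNetwork, list[tuple[int, int]]]:
    """Uniformly remove ``ceil(fraction * positives)`` known pairs.

    Returns the training network and the held-out (drug_index, disease_index)
    list; the two together carry exactly the original positives.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"mask fraction must lie in (0, 1), got {fraction}")
    positives = np.argwhere(net.Y != 0)
    if len(positives) == 0:
        raise ValidationError("network has no positives to mask")
    n_mask = math.ceil(fraction * len(positives))
    if len(positives) - n_mask < 1:
        raise ValidationError("masking would leave no training positives")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positives), size=n_mask, replace=False)
    held_out = [tuple(map(int, positives[c])) for c in sorted(chosen)]
    train = net.copy()
    for i, j in held_out:
        train.Y[i, j] = 0.0
    return train, held_out
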