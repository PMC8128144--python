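"""Weighted K-nearest-known-neighbor (WKNKN) completion of the association matrix.

New drugs and diseases have all-zero interaction profiles, and many recorded
zeros are simply unobserved.  WKNKN replaces each zero entry with an
interaction-likelihood estimate borrowed from the K most similar *known*
neighbors (entities with at least one recorded association), discounted by a
geometric decay: the i-th nearest neighbor contributes with weight
``T**(i-1) * similarity``, normalized by the sum of the neighbor similarities.

The drug-side estimate Y_r and disease-side estimate Y_d are averaged into
Y_rd = (Y_r + Y_d) / 2 and merged with the original matrix as
``max(Y, Y_rd)``, so recorded positives are never weakened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import DrugDiseaseNetwork, SimilarityMatrix
from .errors import ShapeError, ValidationError

__all__ = ["WknknParams", "known_neighbors", "likelihood_profile", "wknkn_complete"]


@dataclass(frozen=True)
class WknknParams:
    """K: neighbor count; T: geometric decay applied per neighbor rank, in (0, 1]."""

    K: int = 5
    T: float = 0.5

    def validate(self) -> "WknknParams":
        if self.K < 1:
            raise ValidationError(f"WKNKN neighbor count K must be >= 1, got {self.K}")
        if not (0.0 < self.T <= 1.0):
            raise ValidationError(f"WKNKN decay T must lie in (0, 1], got {self.T}")
        return self


def _axis_profiles(Y: np.ndarray, axis: str) -> np.ndarray:
    if axis == "drug":
        return Y
    if axis == "disease":
        return Y.T
    raise ValidationError(f"axis must be 'drug' or 'disease', got {axis!r}")


def known_neighbors(
    entity_index: int,
    S: SimilarityMatrix,
    net: DrugDiseaseNetwork,
    axis: str,
    K: int,
) -> list[tuple[int, float]]:
    """Up to K known neighbors of one entity, by descending similarity.

    A neighbor is *known* when its interaction profile has at least one
    nonzero entry.  The entity itself is always excluded.  Ties in similarity
    break toward the lower index; zero-similarity entities may appear (they
    contribute nothing to the weighted profile).
    """
    profiles = _axis_profiles(net.Y, axis)
    p = profiles.shape[0]
    if not (0 <= entity_index < p):
        raise ShapeError(f"entity index {entity_index} out of range for {p} entities")
    known = profiles.any(axis=1)
    candidates = [j for j in range(p) if j != entity_index and known[j]]
    sims = S.S[entity_index]
    candidates.sort(key=lambda j: (-sims[j], j))
    return [(j, float(sims[j])) for j in candidates[:K]]


def likelihood_profile(
    entity_index: int,
    neighbors: list[tuple[int, float]],
    net: DrugDiseaseNetwork,
    T: float,
    axis: str,
) -> np.ndarray:
    """Decay-weighted average of the neighbors' interaction profiles.

    With neighbors ordered by descending similarity, the i-th neighbor (1-based)
    carries weight ``T**(i-1) * s_i`` and the sum is normalized by ``Q = sum s_i``.
    Returns the zero profile when there are no neighbors or Q == 0.
    """
    profiles = _axis_profiles(net.Y, axis)
    out = np.zeros(profiles.shape[1])
    if not neighbors:
        return out
    Q = sum(s for _, s in neighbors)
    if Q <= 0.0:
        return out
    for rank, (j, s) in enumerate(neighbors):
        out += (T**rank) * s * profiles[j]
    return out / Q


def wknkn_complete(
    net: DrugDiseaseNetwork,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    params: WknknParams = WknknParams(),
) -> DrugDiseaseNetwork:
    """Return the completed network ``max(Y, (Y_r + Y_d) / 2)``.

    Y_r stacks the drug-side likelihood profiles; Y_d the disease-side ones.
    The elementwise maximum preserves every recorded association and keeps all
    entries in [0, 1].
    """
    params.validate()
    m, n = net.shape
    if len(S_r.ids) != m or S_r.S.shape != (m, m):
        raise ShapeError("drug similarity does not match the network's drug vocabulary")
    if len(S_d.ids) != n or S_d.S.shape != (n, n):
        raise ShapeError("disease similarity does not match the network's disease vocabulary")
    Yr = np.zeros((m, n))
    for i in range(m):
        nbrs = known_neighbors(i, S_r, net, "drug", params.K)
        Yr[i] = likelihood_profile(i, nbrs, net, params.T, "drug")
    Yd = np.zeros((n, m))
    for j in range(n):
        nbrs = known_neighbors(j, S_d, net, "disease", params.K)
        Yd[j] = likelihood_profile(j, nbrs, net, params.T, "disease")
    Yrd = (Yr + Yd.T) / 2.0
    completed = np.maximum(net.Y, Yrd)
    return DrugDiseaseNetwork(list(net.drug_ids), list(net.disease_ids), completed).validate()
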