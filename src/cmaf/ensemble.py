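"""Noisy-OR fusion of the three base predictors into the final score.

Each base score is read as an independent probability that the pair is a true
association; the fused score is the probability that at least one predictor
fires:

    Rt = 1 - (1 - Y*) (1 - Y**) (1 - Y***)

The fusion dominates each input (Rt >= max of the three), is monotone in each
argument, and maps [0, 1]^3 into [0, 1].  NMF reconstruction scores can
exceed 1 and are clipped (not rescaled) beforehand: clipping is local,
parameter-free, and only touches scores already expressing near-certainty.
"""

from __future__ import annotations

import numpy as np

from .core_data import ScoreMatrix
from .errors import IdentifierError, MatrixValueError

__all__ = ["clip_unit", "fuse_scores"]


def clip_unit(scores: ScoreMatrix) -> ScoreMatrix:
    """Clamp scores into [0, 1]; entries below -1e-9 are a contract violation."""
    if scores.R.size and scores.R.min() < -1e-9:
        raise MatrixValueError(f"negative score {scores.R.min()!r} cannot be clipped to [0, 1]")
    return ScoreMatrix(
        list(scores.drug_ids),
        list(scores.disease_ids),
        np.clip(scores.R, 0.0, 1.0),
        source=scores.source,
    )


def fuse_scores(lp: ScoreMatrix, nmf: ScoreMatrix, ncp: ScoreMatrix) -> ScoreMatrix:
    """Combine LPRIA, NMFRIA and NCPRIA scores by the noisy-OR rule."""
    for other in (nmf, ncp):
        if other.drug_ids != lp.drug_ids or other.disease_ids != lp.disease_ids:
            raise IdentifierError("score matrices are not aligned to the same vocabularies")
    parts = [lp.R, nmf.R, ncp.R]
    for part, name in zip(parts, ("LPRIA", "NMFRIA", "NCPRIA")):
        if part.size and (part.min() < 0.0 or part.max() > 1.0):
            raise MatrixValueError(
                f"{name} scores must lie in [0, 1] before fusion (apply clip_unit)"
            )
    R = 1.0 - (1.0 - parts[0]) * (1.0 - parts[1]) * (1.0 - parts[2])
    return ScoreMatrix(list(lp.drug_ids), list(lp.disease_ids), R, source="CMAF").validate()
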