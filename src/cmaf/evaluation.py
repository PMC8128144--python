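"""Cross-validation, de-novo drug hold-out, ROC/AUC, and candidate ranking.

The harness follows the standard link-prediction protocol: known pairs are
partitioned into folds, each fold's pairs are zeroed out of the training
matrix, the full pipeline (completion -> similarity learning -> predictors ->
fusion) is re-run on the training matrix only, and the held-out positives are
ranked against all pairs that are unknown in the complete matrix.  Training
positives are excluded from evaluation entirely.

AUC is computed as the trapezoidal area under the threshold-swept ROC curve,
which equals the normalized Mann-Whitney statistic with half credit for tied
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .core_data import DrugDiseaseNetwork, ScoreMatrix, SimilarityMatrix
from .errors import IdentifierError, ValidationError

if TYPE_CHECKING:  # circular-at-runtime convenience import
    from .pipeline import PipelineParams

__all__ = [
    "FoldPlan",
    "RocCurve",
    "EvaluationReport",
    "DeNovoReport",
    "make_folds",
    "roc_curve",
    "auc",
    "score_auc",
    "cross_validate",
    "de_novo_drug_test",
    "top_candidates",
]


@dataclass
class FoldPlan:
    """Repeated random partition of the known pairs into near-equal folds.

    ``pairs`` lists the known (drug_index, disease_index) pairs; ``assignments``
    has shape (repeats, n_pairs) and holds each pair's fold label per repeat.
    """

    n_folds: int
    repeats: int
    seed: int
    pairs: np.ndarray  # (n_pairs, 2) int array
    assignments: np.ndarray  # (repeats, n_pairs) int array

    def test_pairs(self, repeat: int, fold: int) -> np.ndarray:
        return self.pairs[self.assignments[repeat] == fold]


@dataclass
class RocCurve:
    """ROC points and the confusion counts behind them, one row per threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class EvaluationReport:
    """Per-fold AUCs with per-repeat and grand means."""

    method: str
    fold_aucs: np.ndarray  # (repeats, n_folds)
    repeat_means: np.ndarray
    grand_mean: float


@dataclass
class DeNovoReport:
    """Pooled AUC over all held-out drugs, plus a per-drug breakdown."""

    method: str
    pooled_auc: float
    per_drug_auc: dict[str, float]


def make_folds(
    net: DrugDiseaseNetwork,
    n_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Randomly partition the known pairs into ``n_folds`` near-equal folds,
    independently for each repeat.  Fold sizes differ by at most one."""
    if n_folds < 2 or repeats < 1:
        raise ValidationError("need n_folds >= 2 and repeats >= 1")
    pairs = np.argwhere(net.Y != 0)
    n_pairs = len(pairs)
    if n_pairs < n_folds:
        raise ValidationError(f"only {n_pairs} known pairs for {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n_pairs), dtype=int)
    base = np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n_pairs, n_folds + 1).astype(int)))
    for rep in range(repeats):
        assignments[rep] = base[rng.permutation(n_pairs)]
    return FoldPlan(n_folds, repeats, seed, pairs, assignments)


def roc_curve(pos_scores, neg_scores) -> RocCurve:
    """Sweep thresholds over the distinct scores, descending.

    At threshold t every score >= t is predicted positive; TP/FP/TN/FN follow.
    The curve starts at (0, 0) (threshold above every score) and ends at (1, 1).
    """
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative score")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # score >= t  <=>  index past the left insertion point of t
    tp = pos.size - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thresholds, side="left")
    tp = np.concatenate([[0], tp])
    fp = np.concatenate([[0], fp])
    thresholds = np.concatenate([[np.inf], thresholds])
    fn = pos.size - tp
    tn = neg.size - fp
    return RocCurve(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        fpr=fp / neg.size,
        tpr=tp / pos.size,
    )


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def score_auc(pos_scores, neg_scores) -> float:
    """AUC of positives vs negatives (ties receive half credit)."""
    return auc(roc_curve(pos_scores, neg_scores))


def _training_network(net: DrugDiseaseNetwork, plan: FoldPlan, repeat: int, fold: int):
    """Binary training matrix rebuilt from the plan's pair list alone.

    Held-out cells are never read, so the evaluation cannot leak their values.
    """
    Y = np.zeros(net.shape)
    train = plan.pairs[plan.assignments[repeat] != fold]
    Y[train[:, 0], train[:, 1]] = 1.0
    return (
        DrugDiseaseNetwork(list(net.drug_ids), list(net.disease_ids), Y),
        plan.pairs[plan.assignments[repeat] == fold],
    )


def cross_validate(
    net: DrugDiseaseNetwork,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    params: "PipelineParams",
    plan: FoldPlan,
    method: str = "CMAF",
) -> EvaluationReport:
    """Run the full pipeline per fold and score held-out positives.

    Per fold, positives are the held-out pairs and negatives are all pairs
    unknown in the complete matrix; per-fold AUCs are averaged within each
    repeat and then across repeats.
    """
    from .pipeline import predict_all  # runtime import to avoid a cycle

    known_mask = np.zeros(net.shape, dtype=bool)
    known_mask[plan.pairs[:, 0], plan.pairs[:, 1]] = True
    neg_idx = np.argwhere(~known_mask)
    fold_aucs = np.empty((plan.repeats, plan.n_folds))
    for rep in range(plan.repeats):
        for fold in range(plan.n_folds):
            train_net, test_pairs = _training_network(net, plan, rep, fold)
            scores = predict_all(train_net, S_r, S_d, params)[method].R
            pos = scores[test_pairs[:, 0], test_pairs[:, 1]]
            neg = scores[neg_idx[:, 0], neg_idx[:, 1]]
            fold_aucs[rep, fold] = score_auc(pos, neg)
    repeat_means = fold_aucs.mean(axis=1)
    return EvaluationReport(method, fold_aucs, repeat_means, float(repeat_means.mean()))


def de_novo_drug_test(
    net: DrugDiseaseNetwork,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    params: "PipelineParams",
    method: str = "CMAF",
) -> DeNovoReport:
    """Hold out each drug's entire association row in turn.

    The pipeline is re-run with the drug's row zeroed; its removed positives
    are ranked against its unknown diseases.  The headline number pools every
    drug's positive and negative scores into a single AUC; per-drug AUCs are
    returned alongside.
    """
    from .pipeline import predict_all

    held_drugs = [i for i in range(net.shape[0]) if net.Y[i].any()]
    if len(held_drugs) < 2:
        raise ValidationError("need at least 2 drugs with known associations")
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    per_drug: dict[str, float] = {}
    for i in held_drugs:
        train = net.copy()
        train.Y[i, :] = 0.0
        row = predict_all(train, S_r, S_d, params)[method].R[i]
        pos = row[net.Y[i] != 0]
        neg = row[net.Y[i] == 0]
        pooled_pos.append(pos)
        if neg.size:
            pooled_neg.append(neg)
            per_drug[net.drug_ids[i]] = score_auc(pos, neg)
    pooled = score_auc(np.concatenate(pooled_pos), np.concatenate(pooled_neg))
    return DeNovoReport(method, pooled, per_drug)


def top_candidates(
    scores: ScoreMatrix,
    net: DrugDiseaseNetwork,
    drug_id: str,
    N: int,
) -> list[tuple[str, float]]:
    """Top-N candidate diseases for one drug, known associations excluded.

    Sorted by score descending; score ties break by disease identifier.
    """
    try:
        i = scores.drug_ids.index(drug_id)
    except ValueError:
        raise IdentifierError(f"unknown drug identifier {drug_id!r}") from None
    if net.drug_ids != scores.drug_ids or net.disease_ids != scores.disease_ids:
        raise IdentifierError("score matrix and network vocabularies are not aligned")
    row = scores.R[i]
    cand = [
        (net.disease_ids[j], float(row[j]))
        for j in range(net.shape[1])
        if net.Y[i, j] == 0
    ]
    cand.sort(key=lambda t: (-t[1], t[0]))
    return cand[:N]
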