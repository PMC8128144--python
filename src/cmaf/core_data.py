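"""Labeled-matrix domain types and TSV input/output.

Three matrix roles circulate through the pipeline:

* :class:`DrugDiseaseNetwork` -- the m x n drug-disease association matrix Y.
  Strictly binary on load; fractional in [0, 1] after nearest-neighbor
  completion.
* :class:`SimilarityMatrix` -- a square pairwise similarity matrix.  Input
  similarities (chemical fingerprints, phenotype text mining) are symmetric
  with unit diagonal; learned linear-neighborhood similarities are
  row-stochastic with zero diagonal and need not be symmetric.
* :class:`ScoreMatrix` -- real-valued prediction scores aligned to the
  network's vocabularies.

The single on-disk dialect is a UTF-8 TSV with a header row of column
identifiers and a leading column of row identifiers.  Identifiers are opaque
strings (DrugBank accessions, OMIM numbers, or anything else); no syntax is
imposed on them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IdentifierError, MatrixValueError, ShapeError

__all__ = [
    "DrugDiseaseNetwork",
    "SimilarityMatrix",
    "ScoreMatrix",
    "load_association_network",
    "load_completed_network",
    "load_similarity_matrix",
    "load_score_matrix",
    "write_matrix",
]

SCORE_SOURCES = ("LPRIA", "NMFRIA", "NCPRIA", "CMAF", "external")
#: score sources whose entries are probabilities and must lie in [0, 1]
_UNIT_SOURCES = ("LPRIA", "NCPRIA", "CMAF")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise IdentifierError(f"duplicate {what} identifier {dup!r}")


@dataclass
class DrugDiseaseNetwork:
    """Bipartite drug-disease association matrix with its two vocabularies.

    ``Y[i, j]`` is the association strength between drug ``drug_ids[i]`` and
    disease ``disease_ids[j]``; row i is the interaction profile of drug i,
    column j the interaction profile of disease j.
    """

    drug_ids: list[str]
    disease_ids: list[str]
    Y: np.ndarray

    def validate(self, binary: bool = False) -> "DrugDiseaseNetwork":
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")
        if self.Y.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ShapeError(
                f"matrix shape {self.Y.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        if not np.all(np.isfinite(self.Y)):
            i, j = np.argwhere(~np.isfinite(self.Y))[0]
            raise MatrixValueError(
                f"non-finite entry at drug {self.drug_ids[i]!r}, "
                f"disease {self.disease_ids[j]!r}"
            )
        if binary:
            bad = (self.Y != 0) & (self.Y != 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MatrixValueError(
                    f"non-binary entry {self.Y[i, j]!r} at drug "
                    f"{self.drug_ids[i]!r}, disease {self.disease_ids[j]!r}; "
                    "association input must be strictly 0/1"
                )
        elif self.Y.size and (self.Y.min() < 0 or self.Y.max() > 1):
            i, j = np.argwhere((self.Y < 0) | (self.Y > 1))[0]
            raise MatrixValueError(
                f"entry {self.Y[i, j]!r} outside [0, 1] at drug "
                f"{self.drug_ids[i]!r}, disease {self.disease_ids[j]!r}"
            )
        return self

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape  # type: ignore[return-value]

    def copy(self) -> "DrugDiseaseNetwork":
        return DrugDiseaseNetwork(list(self.drug_ids), list(self.disease_ids), self.Y.copy())


@dataclass
class SimilarityMatrix:
    """Square pairwise similarity matrix over one entity vocabulary.

    ``kind="input"`` marks externally supplied similarities (symmetric, unit
    diagonal); ``kind="linear_neighborhood"`` marks learned reconstruction
    weights (row-stochastic, zero diagonal, at most K nonzeros per row,
    possibly asymmetric).
    """

    ids: list[str]
    S: np.ndarray
    kind: str = "input"

    def validate(self) -> "SimilarityMatrix":
        _check_unique(self.ids, "entity")
        p = len(self.ids)
        if self.S.shape != (p, p):
            raise ShapeError(f"similarity shape {self.S.shape} does not match {p} ids")
        if not np.all(np.isfinite(self.S)):
            raise MatrixValueError("non-finite similarity entry")
        if self.S.size and (self.S.min() < -1e-9 or self.S.max() > 1 + 1e-9):
            i, j = np.argwhere((self.S < -1e-9) | (self.S > 1 + 1e-9))[0]
            raise MatrixValueError(
                f"similarity {self.S[i, j]!r} outside [0, 1] at "
                f"({self.ids[i]!r}, {self.ids[j]!r})"
            )
        if self.kind == "input":
            if p and np.abs(self.S - self.S.T).max() > 1e-6:
                raise MatrixValueError("input similarity is not symmetric (beyond 1e-6)")
            if p and np.abs(np.diag(self.S) - 1.0).max() > 1e-6:
                raise MatrixValueError("input similarity diagonal deviates from 1")
        elif self.kind == "linear_neighborhood":
            if p and np.abs(self.S.sum(axis=1) - 1.0).max() > 1e-8:
                raise MatrixValueError("linear neighborhood rows must sum to 1")
            if p and np.abs(np.diag(self.S)).max() > 0:
                raise MatrixValueError("linear neighborhood diagonal must be 0")
        else:
            raise MatrixValueError(f"unknown similarity kind {self.kind!r}")
        return self

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.ids), self.S.copy(), self.kind)


@dataclass
class ScoreMatrix:
    """Prediction scores aligned to a network's drug and disease vocabularies."""

    drug_ids: list[str]
    disease_ids: list[str]
    R: np.ndarray
    source: str = "external"

    def validate(self) -> "ScoreMatrix":
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")
        if self.source not in SCORE_SOURCES:
            raise MatrixValueError(f"unknown score source {self.source!r}")
        if self.R.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ShapeError(
                f"score shape {self.R.shape} does not match vocabularies "
                f"({len(self.drug_ids)}, {len(self.disease_ids)})"
            )
        if not np.all(np.isfinite(self.R)):
            raise MatrixValueError("non-finite score entry")
        if self.source in _UNIT_SOURCES and self.R.size and (
            self.R.min() < 0 or self.R.max() > 1
        ):
            raise MatrixValueError(f"{self.source} scores must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# TSV input / output


def _read_labeled_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r]  # drop trailing blank lines
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError(f"{path}: expected a labeled matrix with >=1 row and column")
    col_ids = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    row_ids: list[str] = []
    data: list[list[str]] = []
    for lineno, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(r)} fields, expected {width})")
        row_ids.append(r[0].strip())
        data.append(r[1:])
    values = np.empty((len(row_ids), len(col_ids)), dtype=float)
    for i, row in enumerate(data):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise MatrixValueError(
                    f"{path}: cell at row {row_ids[i]!r}, column {col_ids[j]!r} "
                    f"is not numeric: {cell!r}"
                ) from exc
    return row_ids, col_ids, values


def load_association_network(path) -> DrugDiseaseNetwork:
    """Read a strictly binary drug-disease association matrix from a TSV file."""
    drug_ids, disease_ids, Y = _read_labeled_tsv(path)
    return DrugDiseaseNetwork(drug_ids, disease_ids, Y).validate(binary=True)


def load_completed_network(path) -> DrugDiseaseNetwork:
    """Read a completed (possibly fractional, [0, 1]-valued) association matrix."""
    drug_ids, disease_ids, Y = _read_labeled_tsv(path)
    return DrugDiseaseNetwork(drug_ids, disease_ids, Y).validate(binary=False)


def load_similarity_matrix(
    path,
    expected_ids: Sequence[str],
    kind: str = "input",
) -> SimilarityMatrix:
    """Read a square labeled similarity matrix, aligned to ``expected_ids``.

    The file's identifier set must be a superset of ``expected_ids``; rows and
    columns are reordered (and subset) to that order.  For ``kind="input"``
    small asymmetries (max |S - S^T| <= 1e-6) are repaired by averaging with
    the transpose; larger ones are an error.
    """
    row_ids, col_ids, S = _read_labeled_tsv(path)
    if row_ids != col_ids:
        raise FormatError(f"{path}: row and column identifier lists differ")
    index = {eid: k for k, eid in enumerate(row_ids)}
    missing = [eid for eid in expected_ids if eid not in index]
    if missing:
        raise IdentifierError(f"{path}: missing expected identifiers {missing[:5]}")
    order = [index[eid] for eid in expected_ids]
    S = S[np.ix_(order, order)]
    if S.size and (S.min() < -1e-9 or S.max() > 1 + 1e-9):
        i, j = np.argwhere((S < -1e-9) | (S > 1 + 1e-9))[0]
        raise MatrixValueError(
            f"{path}: similarity {S[i, j]!r} outside [0, 1] at "
            f"({expected_ids[i]!r}, {expected_ids[j]!r})"
        )
    S = np.clip(S, 0.0, 1.0)
    if kind == "input":
        asym = np.abs(S - S.T).max() if S.size else 0.0
        if asym > 1e-6:
            raise MatrixValueError(f"{path}: asymmetry {asym:.3g} exceeds 1e-6 tolerance")
        S = (S + S.T) / 2.0
        if np.abs(np.diag(S) - 1.0).max() > 1e-6:
            raise MatrixValueError(f"{path}: diagonal deviates from 1 beyond 1e-6")
        np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(expected_ids), S, kind=kind).validate()


def load_score_matrix(path, source: str = "external") -> ScoreMatrix:
    """Read a prediction score matrix from a labeled TSV file."""
    drug_ids, disease_ids, R = _read_labeled_tsv(path)
    return ScoreMatrix(drug_ids, disease_ids, R, source=source).validate()


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, DrugDiseaseNetwork):
        return pd.DataFrame(matrix.Y, index=matrix.drug_ids, columns=matrix.disease_ids)
    if isinstance(matrix, SimilarityMatrix):
        return pd.DataFrame(matrix.S, index=matrix.ids, columns=matrix.ids)
    if isinstance(matrix, ScoreMatrix):
        return pd.DataFrame(matrix.R, index=matrix.drug_ids, columns=matrix.disease_ids)
    raise TypeError(f"cannot serialize object of type {type(matrix).__name__}")


def write_matrix(matrix, path) -> None:
    """Write any matrix role as a labeled TSV at full double precision.

    Values are rendered with Python's shortest round-trip ``repr`` so that
    ``load(write(x))`` reproduces ``x`` bit for bit.
    """
    frame = _as_frame(matrix)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError("refusing to write an empty matrix")
    buf = io.StringIO()
    buf.write("\t" + "\t".join(map(str, frame.columns)) + "\n")
    values = frame.to_numpy()
    for rid, row in zip(frame.index, values):
        buf.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
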