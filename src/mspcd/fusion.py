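"""Flag-gated fusion of the base similarities.

For a circRNA pair the fused score is the mean of sequence and functional
similarity when both circRNAs have sequences, and the interaction-profile
kernel otherwise.  For a disease pair it is the mean of the two DAG
semantic scores when both diseases sit in the vocabulary DAG, and the
disease kernel otherwise.  The binary flag matrices FQ (sequence
availability) and FS (DAG coverage) select the branch per entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataio import DiseaseDAG, SequenceSet, SimilarityMatrix
from .errors import ValidationError

__all__ = [
    "FlagMatrix",
    "build_sequence_flags",
    "build_semantic_flags",
    "fuse_circrna",
    "fuse_disease",
]


@dataclass
class FlagMatrix:
    """Symmetric binary availability matrix over an ordered id list."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("flag matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("flag matrix shape does not match ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("flag matrix must be symmetric")


def _coverage_flags(covered: Sequence[bool], ids: Sequence[str]) -> FlagMatrix:
    c = np.asarray(covered, dtype=np.int8)
    return FlagMatrix(np.outer(c, c), list(ids))


def build_sequence_flags(seqs: SequenceSet, ids: Sequence[str]) -> FlagMatrix:
    """FQ(m, n) = 1 iff both circRNAs have a sequence (diagonal included)."""
    return _coverage_flags([i in seqs for i in ids], ids)


def build_semantic_flags(dag: DiseaseDAG, ids: Sequence[str]) -> FlagMatrix:
    """FS(m, n) = 1 iff both diseases are nodes of the DAG."""
    return _coverage_flags([d in dag for d in ids], ids)


def _check_ids(*items: SimilarityMatrix | FlagMatrix) -> list[str]:
    ids = items[0].ids
    for it in items[1:]:
        if it.ids != ids:
            raise ValidationError("fusion inputs disagree on ids or their order")
    return list(ids)


def fuse_circrna(
    CS: SimilarityMatrix,
    CF: SimilarityMatrix,
    CG: SimilarityMatrix,
    FQ: FlagMatrix,
) -> SimilarityMatrix:
    """Fused circRNA similarity: (CS + CF) / 2 where sequences exist for
    both circRNAs, the interaction-profile kernel CG elsewhere."""
    ids = _check_ids(CS, CF, CG, FQ)
    mask = FQ.values.astype(bool)
    values = np.where(mask, (CS.values + CF.values) / 2.0, CG.values)
    return SimilarityMatrix(values, ids, "CV")


def fuse_disease(
    DS1: SimilarityMatrix,
    DS2: SimilarityMatrix,
    DG: SimilarityMatrix,
    FS: FlagMatrix,
) -> SimilarityMatrix:
    """Fused disease similarity: (DS1 + DS2) / 2 where both diseases are
    DAG-covered, the disease kernel DG elsewhere.

    Under the ``as_printed`` model-2 convention fused entries can exceed
    1; they are reported, not clipped, so the convention's effect stays
    visible.
    """
    ids = _check_ids(DS1, DS2, DG, FS)
    mask = FS.values.astype(bool)
    values = np.where(mask, (DS1.values + DS2.values) / 2.0, DG.values)
    vmax = values.max(initial=0.0)
    if vmax > 1.0 + 1e-12:
        warnings.warn(
            f"fused disease similarity exceeds 1 (max {vmax:.6g}); "
            "this happens under the as_printed model-2 denominator",
            stacklevel=2,
        )
    return SimilarityMatrix(values, ids, "DV")
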