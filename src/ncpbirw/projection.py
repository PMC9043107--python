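"""Network-consistency projection of similarity vectors onto association
profiles.

The lncRNA-side score projects lncRNA i's integrated-similarity row onto
disease j's association column; the disease-side score projects disease j's
similarity column onto lncRNA i's association row. Each is normalized by the
Euclidean norm of the association vector (sqrt of its 1-count for binary
data), so a smaller angle between the two vectors yields a higher score.
Entities with no known associations have zero-norm vectors; their scores are
defined as 0 rather than raising, because cross-validation masking routinely
produces them.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    AssociationMatrix,
    ProjectionScores,
    SimilarityMatrix,
    ValidationError,
)

__all__ = ["lncrna_projection", "disease_projection"]


def lncrna_projection(
    LS: SimilarityMatrix, A: AssociationMatrix
) -> ProjectionScores:
    """Project each lncRNA similarity row onto each disease's association
    column: ``(LS_i . A_j) / ||A_j||``, 0 where the column is all-zero."""
    if LS.entity_ids != A.lncrna_ids:
        raise ValidationError(
            "LS is not indexed by the association matrix's lncRNA ids"
        )
    col_norms = np.linalg.norm(A.values, axis=0)
    scores = LS.values @ A.values
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(col_norms > 0.0, scores / col_norms, 0.0)
    return ProjectionScores(scores, side="lncrna")


def disease_projection(
    DS: SimilarityMatrix, A: AssociationMatrix
) -> ProjectionScores:
    """Project each disease similarity column onto each lncRNA's association
    row: ``(A_i . DS_j) / ||A_i||``, 0 where the row is all-zero."""
    if DS.entity_ids != A.disease_ids:
        raise ValidationError(
            "DS is not indexed by the association matrix's disease ids"
        )
    row_norms = np.linalg.norm(A.values, axis=1)
    scores = A.values @ DS.values
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(row_norms[:, None] > 0.0,
                          scores / row_norms[:, None], 0.0)
    return ProjectionScores(scores, side="disease")
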