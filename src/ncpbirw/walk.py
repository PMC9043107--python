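"""Normalization and the projection-augmented bi-random walk.

The score matrix diffuses simultaneously through the normalized lncRNA
similarity network (left multiplication) and the normalized disease
similarity network (right multiplication). Each side mixes the diffused
scores with a restart term built from the association matrix plus that
side's network-consistency projection scores, weighted by the decay factor
beta. Iteration counts r1 (lncRNA side) and r2 (disease side) are fixed and
small; the walk ends at t = max(r1, r2).

Two normalizations of a similarity matrix M are available: the ``literal``
product form ``M(i,j) / (colsum_j(M) * rowsum_i(M))`` and its square-root
(``sqrt``) symmetric variant, which is the one that actually keeps values
within [0, 1].
"""

from __future__ import annotations

import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDagSet,
    ProjectionScores,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
    WalkParams,
)
from .projection import disease_projection, lncrna_projection
from .similarity import (
    disease_semantic_similarity,
    gip_kernel,
    integrate_disease,
    integrate_lncrna,
    lncrna_functional_similarity,
)

__all__ = [
    "normalize_similarity",
    "normalize_association",
    "birw_scores",
    "predict",
]


def normalize_similarity(M: np.ndarray | SimilarityMatrix,
                         variant: str = "literal") -> np.ndarray:
    """Normalize a non-negative matrix by the product of its row and column
    sums (``literal``) or by the square root of that product (``sqrt``).

    Entries whose row or column sum is zero map to 0.
    """
    values = M.values if isinstance(M, SimilarityMatrix) else np.asarray(M, dtype=float)
    if (values < 0).any():
        raise ValidationError("normalize_similarity requires a non-negative matrix")
    if variant not in ("literal", "sqrt"):
        raise ValidationError(f"unknown normalization variant {variant!r}")
    row_sums = values.sum(axis=1)  # sum over j of M(i, j)
    col_sums = values.sum(axis=0)  # sum over i of M(i, j)
    denom = row_sums[:, None] * col_sums[None, :]
    if variant == "sqrt":
        denom = np.sqrt(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0.0, values / denom, 0.0)
    return out


def normalize_association(A: AssociationMatrix | np.ndarray) -> np.ndarray:
    """Initial probability matrix: A divided by its grand total."""
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    total = values.sum()
    if total == 0:
        raise ValidationError(
            "association matrix has no positive entries; "
            "the initial probability matrix is undefined"
        )
    return values / total


def _restart_term(A_values: np.ndarray, ncp_values: np.ndarray) -> np.ndarray:
    combined = A_values + ncp_values
    total = combined.sum()
    if total == 0:
        raise ValidationError(
            "association + projection scores sum to zero (empty network)"
        )
    return combined / total


def birw_scores(
    NLS: np.ndarray,
    NDS: np.ndarray,
    A: AssociationMatrix,
    LSNCP: ProjectionScores | np.ndarray,
    DSNCP: ProjectionScores | np.ndarray,
    params: WalkParams,
) -> ScoreMatrix:
    """Run the projection-augmented bi-random walk and return final scores.

    Per iteration t (Jacobi-style, both sides reading S(t-1)):

    * lncRNA side, while t <= r1:
      ``RL = beta * NLS @ S(t-1) + (1-beta) * (A + LSNCP)/sum(A + LSNCP)``
    * disease side, while t <= r2:
      ``RD = beta * S(t-1) @ NDS + (1-beta) * (A + DSNCP)/sum(A + DSNCP)``
    * ``S(t) = (RL + RD) / 2``

    When one side's iteration cap is exhausted (possible only for r1 != r2)
    the default ``freeze`` policy lets it contribute S(t-1); the ``active``
    policy averages only the still-iterating side.

    ``mode="ncp_only"`` skips the walk and averages the two restart terms;
    ``mode="birw_only"`` replaces both projection restart terms with the
    normalized association matrix.
    """
    lsncp = LSNCP.values if isinstance(LSNCP, ProjectionScores) else np.asarray(LSNCP)
    dsncp = DSNCP.values if isinstance(DSNCP, ProjectionScores) else np.asarray(DSNCP)
    shape = A.values.shape
    for name, m in (("NLS", NLS), ("NDS", NDS)):
        if np.asarray(m).shape[0] != np.asarray(m).shape[1]:
            raise ValidationError(f"{name} must be square")
    if NLS.shape[0] != shape[0] or NDS.shape[0] != shape[1]:
        raise ValidationError("similarity network shapes do not match A")
    if lsncp.shape != shape or dsncp.shape != shape:
        raise ValidationError("projection score shapes do not match A")

    if params.mode == "birw_only":
        restart_l = restart_d = normalize_association(A)
    else:
        restart_l = _restart_term(A.values, lsncp)
        restart_d = _restart_term(A.values, dsncp)

    if params.mode == "ncp_only":
        return ScoreMatrix(A.lncrna_ids, A.disease_ids,
                           0.5 * (restart_l + restart_d))

    beta = params.beta
    S = normalize_association(A)
    for t in range(1, max(params.r1, params.r2) + 1):
        l_active = t <= params.r1
        d_active = t <= params.r2
        RL = beta * (NLS @ S) + (1.0 - beta) * restart_l if l_active else S
        RD = beta * (S @ NDS) + (1.0 - beta) * restart_d if d_active else S
        if params.exhausted_policy == "active":
            sides = [m for m, active in ((RL, l_active), (RD, d_active))
                     if active]
            S = sum(sides) / len(sides)
        else:
            S = 0.5 * (RL + RD)
    return ScoreMatrix(A.lncrna_ids, A.disease_ids, S)


def predict(
    A: AssociationMatrix,
    dag_set: DiseaseDagSet,
    params: WalkParams | None = None,
    gamma_prime_l: float = 1.0,
    gamma_prime_d: float = 1.0,
    bandwidth_convention: str = "divide",
) -> ScoreMatrix:
    """Full pipeline: similarities -> integration -> projection -> walk.

    Deterministic given its inputs. Returns the final score matrix aligned
    with ``A``.
    """
    params = params or WalkParams()
    KL = gip_kernel(A, "lncrna", gamma_prime_l, bandwidth_convention)
    KD = gip_kernel(A, "disease", gamma_prime_d, bandwidth_convention)
    SV = disease_semantic_similarity(dag_set, A.disease_ids)
    FL = lncrna_functional_similarity(A, SV)
    LS = integrate_lncrna(KL, FL)
    DS = integrate_disease(KD, SV)
    lsncp = lncrna_projection(LS, A)
    dsncp = disease_projection(DS, A)
    NLS = normalize_similarity(LS, params.normalization_variant)
    NDS = normalize_similarity(DS, params.normalization_variant)
    return birw_scores(NLS, NDS, A, lsncp, dsncp, params)
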