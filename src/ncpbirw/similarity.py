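"""Similarity kernels over lncRNAs and diseases, and their fusion.

Four base matrices feed the predictor:

* ``KL`` / ``KD`` — Gaussian interaction-profile (GIP) kernels over the rows
  (lncRNAs) and columns (diseases) of the binary association matrix,
  ``exp(-gamma * ||IP_i - IP_j||^2)`` with the bandwidth gamma normalized by
  the mean squared profile norm;
* ``SV`` — disease semantic similarity from MeSH-style ancestor DAGs, with a
  per-generation decay ``delta`` plus a rarity bonus for ancestor terms that
  appear in few DAGs;
* ``FL`` — lncRNA functional similarity: best-match average of ``SV`` across
  the two lncRNAs' associated-disease sets.

The integrated matrices ``LS`` and ``DS`` average the GIP kernel with the
biological similarity wherever the latter is informative (non-zero) and fall
back to the kernel elsewhere.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDagSet,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "gip_kernel",
    "semantic_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "lncrna_functional_similarity",
    "integrate_lncrna",
    "integrate_disease",
]

logger = logging.getLogger(__name__)


def gip_kernel(
    A: AssociationMatrix,
    side: str,
    gamma_prime: float = 1.0,
    bandwidth_convention: str = "divide",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one side of ``A``.

    Profiles are rows of ``A`` for ``side="lncrna"``, columns for
    ``side="disease"``. The kernel is ``exp(-gamma * ||IP_i - IP_j||^2)``
    with ``gamma = gamma_prime / mean_i ||IP_i||^2`` under the default
    ``"divide"`` bandwidth convention (the normalized-bandwidth convention of
    the GIP-kernel literature); ``"multiply"`` uses
    ``gamma_prime * mean_i ||IP_i||^2`` instead.

    If every profile is all-zero the bandwidth is undefined; the identity
    matrix is returned with a logged warning.
    """
    if gamma_prime <= 0:
        raise ValidationError(f"gamma_prime must be > 0, got {gamma_prime}")
    if side == "lncrna":
        profiles, ids = A.values, A.lncrna_ids
    elif side == "disease":
        profiles, ids = A.values.T, A.disease_ids
    else:
        raise ValidationError(f"unknown GIP side {side!r}")
    if bandwidth_convention not in ("divide", "multiply"):
        raise ValidationError(
            f"unknown bandwidth convention {bandwidth_convention!r}"
        )
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = float(sq_norms.mean())
    if mean_sq == 0.0:
        logger.warning(
            "GIP %s kernel: all profiles are zero; returning identity", side
        )
        return SimilarityMatrix(ids, np.eye(len(ids)), name=f"GIP_{side}")
    if bandwidth_convention == "divide":
        gamma = gamma_prime / mean_sq
    else:
        gamma = gamma_prime * mean_sq
    # ||x - y||^2 expanded via the Gram matrix; exact for binary profiles
    gram = profiles @ profiles.T
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    values = np.exp(-gamma * sq_dist)
    return SimilarityMatrix(ids, values, name=f"GIP_{side}").symmetrized()


def semantic_contribution(dag_set: DiseaseDagSet, d: str) -> dict[str, float]:
    """Semantic contribution ``Dd(s)`` of every ancestor ``s`` to disease ``d``.

    ``Dd(d) = 1``; for any proper ancestor ``s`` the contribution is the
    maximum over its children ``s'`` inside DAG(d) of
    ``(delta + P_s) * Dd(s')``, where the frequency bonus
    ``P_s = (max_k dags(k) - dags(s)) / D`` rewards terms appearing in few
    DAGs of the vocabulary.
    """
    members = dag_set.ancestor_set(d)
    max_count = dag_set.max_dag_count
    total = dag_set.total_diseases

    contrib: dict[str, float] = {}

    def value(s: str) -> float:
        if s in contrib:
            return contrib[s]
        if s == d:
            contrib[s] = 1.0
            return 1.0
        children = [c for c in dag_set.children_within(d, s) if c in members]
        if not children:
            # closure guarantees a descendant path to d; defensive guard
            raise ValidationError(
                f"node {s!r} in DAG({d!r}) has no children inside the DAG"
            )
        p_s = (max_count - dag_set.dag_counts[s]) / total
        contrib[s] = max((dag_set.delta + p_s) * value(c) for c in children)
        return contrib[s]

    for s in members:
        value(s)
    return contrib


def semantic_value(dag_set: DiseaseDagSet, d: str) -> float:
    """Total semantic value ``DV(d)``: sum of ``Dd(s)`` over ancestors."""
    return float(sum(semantic_contribution(dag_set, d).values()))


def disease_semantic_similarity(
    dag_set: DiseaseDagSet, diseases: tuple[str, ...] | list[str]
) -> SimilarityMatrix:
    """Pairwise semantic similarity ``SV`` over the listed diseases.

    ``SV(di, dj)`` sums ``Ddi(s) + Ddj(s)`` over the shared ancestors
    ``s in N(di) & N(dj)`` and normalizes by ``DV(di) + DV(dj)``; it is 1 on
    the diagonal and 0 for diseases with disjoint DAGs.

    A disease absent from the DAG set gets similarity 0 to every other
    disease (diagonal 1), equivalent to an isolated singleton DAG; this is
    logged once per call.
    """
    diseases = tuple(diseases)
    missing = [d for d in diseases if d not in dag_set]
    if missing:
        logger.warning(
            "%d disease(s) lack a DAG entry (e.g. %s); their semantic "
            "similarity rows are zero off-diagonal",
            len(missing), missing[:3],
        )
    contribs = {d: semantic_contribution(dag_set, d) for d in diseases
                if d in dag_set}
    dvs = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        di = diseases[i]
        if di not in contribs:
            continue
        for j in range(i + 1, n):
            dj = diseases[j]
            if dj not in contribs:
                continue
            shared = contribs[di].keys() & contribs[dj].keys()
            if not shared:
                continue
            num = sum(contribs[di][s] + contribs[dj][s] for s in shared)
            values[i, j] = values[j, i] = num / (dvs[di] + dvs[dj])
    return SimilarityMatrix(diseases, values, name="SV")


def lncrna_functional_similarity(
    A: AssociationMatrix, SV: SimilarityMatrix
) -> SimilarityMatrix:
    """Best-match-average functional similarity ``FL`` between lncRNAs.

    For lncRNAs with disease sets ``D(li)``, ``D(lj)`` the similarity is the
    sum over each disease in either set of its best semantic match in the
    other set, divided by ``|D(li)| + |D(lj)|``. lncRNAs with an empty
    disease set get similarity 0 to everything, including themselves.
    """
    if SV.entity_ids != A.disease_ids:
        raise ValidationError(
            "semantic similarity matrix is not indexed by the association "
            "matrix's disease ids"
        )
    nl = A.n_lncrna
    disease_sets = [np.nonzero(A.values[i])[0] for i in range(nl)]
    values = np.zeros((nl, nl))
    for i in range(nl):
        Di = disease_sets[i]
        if Di.size == 0:
            continue
        values[i, i] = 1.0  # Eq. analytically yields 1; assert by definition
        for j in range(i + 1, nl):
            Dj = disease_sets[j]
            if Dj.size == 0:
                continue
            block = SV.values[np.ix_(Di, Dj)]
            best_i = block.max(axis=1)  # each of D(li) vs best in D(lj)
            best_j = block.max(axis=0)
            values[i, j] = values[j, i] = (
                (best_i.sum() + best_j.sum()) / (Di.size + Dj.size)
            )
    return SimilarityMatrix(A.lncrna_ids, values, name="FL")


def _integrate(
    kernel: SimilarityMatrix, other: SimilarityMatrix, name: str
) -> SimilarityMatrix:
    if kernel.entity_ids != other.entity_ids:
        raise ValidationError(
            f"{name}: the two similarity matrices index different entities"
        )
    values = np.where(
        other.values != 0.0,
        0.5 * (kernel.values + other.values),
        kernel.values,
    )
    return SimilarityMatrix(kernel.entity_ids, values, name=name)


def integrate_lncrna(
    KL: SimilarityMatrix, FL: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated lncRNA similarity ``LS``: mean of GIP kernel and functional
    similarity where the latter is non-zero, GIP kernel otherwise."""
    return _integrate(KL, FL, "LS")


def integrate_disease(
    KD: SimilarityMatrix, SV: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated disease similarity ``DS``: mean of GIP kernel and semantic
    similarity where the latter is non-zero, GIP kernel otherwise."""
    return _integrate(KD, SV, "DS")
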