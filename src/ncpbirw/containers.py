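"""In-memory containers shared across the pipeline.

The central objects are :class:`AssociationMatrix` (a binary lncRNA x disease
incidence matrix with stable entity orderings), :class:`SimilarityMatrix`
(a square symmetric non-negative matrix keyed to one entity set) and
:class:`DiseaseDagSet` (per-disease MeSH-style ancestor DAGs plus global
DAG-membership counts). All matrices are dense float64 numpy arrays: the
study-scale problems (tens of lncRNAs by hundreds of diseases) never warrant
sparse storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDagSet",
    "WalkParams",
    "ProjectionScores",
    "ScoreMatrix",
    "ValidationError",
]

#: absolute tolerance used for symmetry / range checks
SYM_TOL = 1e-10


class ValidationError(ValueError):
    """An input object violates one of its structural invariants."""


def _check_unique(ids: tuple[str, ...], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary lncRNA x disease incidence matrix.

    Rows are lncRNAs in ``lncrna_ids`` order, columns diseases in
    ``disease_ids`` order; entry (i, j) is 1 iff the pair is a known
    (experimentally validated) association.
    """

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        if values.ndim != 2:
            raise ValidationError("association values must be a 2-D matrix")
        nl, nd = values.shape
        if nl != len(self.lncrna_ids) or nd != len(self.disease_ids):
            raise ValidationError(
                f"shape {values.shape} does not match id lists "
                f"({len(self.lncrna_ids)}, {len(self.disease_ids)})"
            )
        if nl < 1 or nd < 1:
            raise ValidationError("association matrix must be at least 1x1")
        _check_unique(self.lncrna_ids, "lncRNA")
        _check_unique(self.disease_ids, "disease")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValidationError("association entries must be 0 or 1")

    @property
    def n_lncrna(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def lncrna_index(self, lncrna_id: str) -> int:
        try:
            return self.lncrna_ids.index(lncrna_id)
        except ValueError:
            raise KeyError(f"unknown lncRNA id: {lncrna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Return a copy of this matrix with replaced entries (same ids)."""
        return AssociationMatrix(self.lncrna_ids, self.disease_ids, values)

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Row/column index pairs of all 1-entries, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric non-negative similarity matrix over one entity set."""

    entity_ids: tuple[str, ...]
    values: np.ndarray
    #: label for error messages and summaries, e.g. "KL", "SV"
    name: str = "similarity"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        n = len(self.entity_ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"{self.name}: shape {values.shape} does not match {n} ids"
            )
        _check_unique(self.entity_ids, self.name)
        if not np.isfinite(values).all():
            raise ValidationError(f"{self.name}: non-finite entries")
        if (values < -SYM_TOL).any():
            raise ValidationError(f"{self.name}: negative entries")
        if np.abs(values - values.T).max(initial=0.0) > SYM_TOL:
            raise ValidationError(f"{self.name}: matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def symmetrized(self) -> "SimilarityMatrix":
        """Average the matrix with its transpose (floating-point hygiene)."""
        v = 0.5 * (self.values + self.values.T)
        return SimilarityMatrix(self.entity_ids, np.clip(v, 0.0, None), self.name)


@dataclass(frozen=True)
class DiseaseDagSet:
    """Per-disease ancestor DAGs over a shared disease vocabulary.

    Each disease ``d`` owns ``DAG(d) = (d, N(d), E(d))`` where ``N(d)`` is the
    ancestor closure of ``d`` (including ``d`` itself) and ``E(d)`` the
    parent->child edges among those ancestors. ``dag_counts[s]`` is the number
    of DAGs in the vocabulary that contain node ``s`` and ``total_diseases``
    is the vocabulary size ``D`` entering the contribution-frequency term.
    """

    #: disease id -> parent->child edge list of its ancestor DAG
    edges: dict[str, tuple[tuple[str, str], ...]]
    dag_counts: dict[str, int]
    total_diseases: int
    #: per-generation semantic decay factor
    delta: float = 0.5
    nodes: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValidationError(f"delta must lie in (0, 1), got {self.delta}")
        if self.total_diseases < 1:
            raise ValidationError("total_diseases must be >= 1")
        nodes: dict[str, frozenset[str]] = {}
        for d, edge_list in self.edges.items():
            g = nx.DiGraph()
            g.add_node(d)
            g.add_edges_from(edge_list)
            if not nx.is_directed_acyclic_graph(g):
                raise ValidationError(f"DAG for disease {d!r} contains a cycle")
            # every node must be an ancestor of d (closure under ancestry):
            # walking child->parent from d must reach the whole node set
            reachable = nx.ancestors(g, d) | {d}
            if reachable != set(g.nodes):
                stray = sorted(set(g.nodes) - reachable)
                raise ValidationError(
                    f"DAG for disease {d!r}: nodes {stray[:5]} are not "
                    "ancestors of the disease (closure violated)"
                )
            nodes[d] = frozenset(g.nodes)
        object.__setattr__(self, "nodes", nodes)
        for d, members in nodes.items():
            missing = sorted(members - self.dag_counts.keys())
            if missing:
                raise ValidationError(
                    f"DAG for disease {d!r}: nodes {missing[:5]} missing "
                    "from the dag-membership count table"
                )
        for s, c in self.dag_counts.items():
            if not 1 <= c <= self.total_diseases:
                raise ValidationError(
                    f"dag_counts[{s!r}] = {c} outside [1, {self.total_diseases}]"
                )

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.edges)

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(self.dag_counts)

    @property
    def max_dag_count(self) -> int:
        return max(self.dag_counts.values())

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.edges

    def ancestor_set(self, disease_id: str) -> frozenset[str]:
        try:
            return self.nodes[disease_id]
        except KeyError:
            raise KeyError(f"no DAG for disease {disease_id!r}") from None

    def children_within(self, disease_id: str, node: str) -> tuple[str, ...]:
        """Children of ``node`` inside DAG(disease_id)."""
        return tuple(c for p, c in self.edges[disease_id] if p == node)


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the NCP-augmented bi-random walk.

    beta is the decay factor balancing diffusion against the restart
    (projection) term; r1 and r2 cap the iterations on the lncRNA and
    disease similarity networks.
    """

    beta: float = 0.8
    r1: int = 1
    r2: int = 1
    #: Eq-literal product normalization vs its square-root (symmetric) variant
    normalization_variant: str = "literal"
    #: full model, projection-only, or plain bi-random walk ablation
    mode: str = "full"
    #: when r1 != r2 and one walk is exhausted: "freeze" it at S(t-1) or
    #: average only the "active" walks
    exhausted_policy: str = "freeze"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValidationError(f"beta must lie in [0, 1], got {self.beta}")
        if self.r1 < 1 or self.r2 < 1:
            raise ValidationError("r1 and r2 must be >= 1")
        if self.normalization_variant not in ("literal", "sqrt"):
            raise ValidationError(
                f"unknown normalization variant {self.normalization_variant!r}"
            )
        if self.mode not in ("full", "ncp_only", "birw_only"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.exhausted_policy not in ("freeze", "active"):
            raise ValidationError(
                f"unknown exhausted policy {self.exhausted_policy!r}"
            )


@dataclass(frozen=True)
class ProjectionScores:
    """Network-consistency projection scores, one matrix per side."""

    values: np.ndarray
    side: str  # "lncrna" or "disease"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.side not in ("lncrna", "disease"):
            raise ValidationError(f"unknown projection side {self.side!r}")
        if not np.isfinite(values).all():
            raise ValidationError("projection scores must be finite")
        if (values < -SYM_TOL).any():
            raise ValidationError("projection scores must be non-negative")


@dataclass(frozen=True)
class ScoreMatrix:
    """Dense real-valued score matrix aligned with an AssociationMatrix."""

    lncrna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lncrna_ids", tuple(self.lncrna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        if values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValidationError("score matrix shape does not match id lists")
        if not np.isfinite(values).all():
            raise ValidationError("score matrix entries must be finite")
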