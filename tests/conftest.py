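"""Shared fixtures: micro DAG fixtures, random instance factories, and a
session-scoped planted benchmark dataset."""

from __future__ import annotations

import numpy as np
import pytest

from ncpbirw.containers import AssociationMatrix, DiseaseDagSet
from ncpbirw.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture
def two_node_dagset() -> DiseaseDagSet:
    """d2 has parent d1; d1 appears in both DAGs, d2 only in its own."""
    return DiseaseDagSet(
        edges={"d1": (), "d2": (("d1", "d2"),)},
        dag_counts={"d1": 2, "d2": 1},
        total_diseases=2,
    )


@pytest.fixture
def identity_assoc() -> AssociationMatrix:
    return AssociationMatrix(("L1", "L2"), ("D1", "D2"), np.eye(2))


def random_association(rng: np.random.Generator, nl: int, nd: int,
                       density: float = 0.4) -> AssociationMatrix:
    """Random binary matrix guaranteed to contain at least one 1."""
    values = (rng.random((nl, nd)) < density).astype(float)
    if values.sum() == 0:
        values[rng.integers(nl), rng.integers(nd)] = 1.0
    return AssociationMatrix(
        tuple(f"L{i}" for i in range(nl)),
        tuple(f"D{j}" for j in range(nd)),
        values,
    )


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric non-negative matrix with unit diagonal."""
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m


def random_dag_forest(rng: np.random.Generator, n_nodes: int) -> DiseaseDagSet:
    """Random multi-parent DAG forest over n_nodes diseases.

    Node i may take up to two parents among nodes with smaller index, which
    guarantees acyclicity; each disease's DAG is the ancestor closure of the
    node in the global hierarchy, and dag_counts are exact membership counts.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    parents: dict[str, list[str]] = {names[0]: []}
    for i in range(1, n_nodes):
        k = int(rng.integers(0, 3))
        k = min(k, i)
        parents[names[i]] = (
            list(rng.choice(names[:i], size=k, replace=False)) if k else []
        )

    def closure(d: str) -> set[str]:
        seen, stack = {d}, [d]
        while stack:
            for p in parents[stack.pop()]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    edges: dict[str, tuple[tuple[str, str], ...]] = {}
    members: dict[str, set[str]] = {}
    for d in names:
        mem = closure(d)
        members[d] = mem
        edges[d] = tuple(
            (p, c) for c in mem for p in parents[c] if p in mem
        )
    counts = {s: sum(s in mem for mem in members.values()) for s in names}
    return DiseaseDagSet(edges=edges, dag_counts=counts,
                         total_diseases=n_nodes)


@pytest.fixture(scope="session")
def planted():
    """Study-scale planted benchmark: ~700 edges in an 82x157 matrix."""
    return simulate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_planted():
    """Fast planted benchmark for unit-level checks."""
    cfg = SyntheticConfig(n_lncrna=20, n_disease=30, n_blocks=4,
                          within_block_density=0.5,
                          background_density=0.01, dag_depth=2, seed=7)
    return simulate_dataset(cfg)
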