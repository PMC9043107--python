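"""Readers and writers for the plain-text formats the tool consumes.

All files are UTF-8 TSV. Entity ordering is always first-appearance order in
the input file, which keeps every downstream matrix reproducible without
imposing a sort. Identifier matching is case-sensitive exact string match;
no synonym resolution is attempted.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AssociationMatrix,
    DiseaseDagSet,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "read_association_list",
    "write_association_list",
    "read_dag_set",
    "write_dag_set",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_ranked_predictions",
    "ranked_predictions",
]

logger = logging.getLogger(__name__)

TOTAL_DISEASES_KEY = "total_diseases"


def read_association_list(
    path: str | Path, delimiter: str = "\t", header: bool = False
) -> AssociationMatrix:
    """Read a two-column (lncRNA id, disease id) edge list into a matrix.

    Duplicate pairs collapse to a single 1 (the number collapsed is logged);
    row and column order follow first appearance of each id.

    Parameters
    ----------
    path : file path of the edge list.
    delimiter : column separator, tab by default.
    header : skip the first row when True.
    """
    lnc_order: dict[str, int] = {}
    dis_order: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ValidationError(
                    f"{path}: line {lineno}: expected two non-empty columns, "
                    f"got {row!r}"
                )
            lnc, dis = row[0].strip(), row[1].strip()
            lnc_order.setdefault(lnc, len(lnc_order))
            dis_order.setdefault(dis, len(dis_order))
            pairs.add((lnc, dis))
            n_rows += 1
    if not pairs:
        raise ValidationError(f"{path}: no association rows found")
    if n_rows > len(pairs):
        logger.info(
            "%s: collapsed %d duplicate pair(s)", path, n_rows - len(pairs)
        )
    values = np.zeros((len(lnc_order), len(dis_order)))
    for lnc, dis in pairs:
        values[lnc_order[lnc], dis_order[dis]] = 1.0
    return AssociationMatrix(tuple(lnc_order), tuple(dis_order), values)


def write_association_list(A: AssociationMatrix, path: str | Path) -> None:
    """Write the positive pairs of ``A`` as a two-column TSV edge list.

    Pairs are emitted in row-major matrix order so that reading the file back
    reproduces the same entity orderings.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, j in A.positive_pairs():
            writer.writerow([A.lncrna_ids[i], A.disease_ids[j]])


def read_dag_set(
    edges_path: str | Path,
    counts_path: str | Path,
    delta: float = 0.5,
) -> DiseaseDagSet:
    """Read per-disease ancestor-closure DAGs and the membership count table.

    The edges file has rows ``disease_id <TAB> parent_id <TAB> child_id``;
    a row whose parent and child columns are empty declares a disease with a
    singleton DAG (no ancestors). The counts file has rows
    ``node_id <TAB> dag_count`` and may carry the vocabulary size as a
    ``# total_diseases=<int>`` comment line; when absent, the number of
    declared DAGs is used.
    """
    edges: dict[str, list[tuple[str, str]]] = {}
    with open(edges_path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            row = [c.strip() for c in row]
            if not row[0]:
                raise ValidationError(
                    f"{edges_path}: line {lineno}: empty disease id"
                )
            disease = row[0]
            edges.setdefault(disease, [])
            parent = row[1] if len(row) > 1 else ""
            child = row[2] if len(row) > 2 else ""
            if parent or child:
                if not (parent and child):
                    raise ValidationError(
                        f"{edges_path}: line {lineno}: edge rows need both "
                        "parent and child ids"
                    )
                edges[disease].append((parent, child))
    if not edges:
        raise ValidationError(f"{edges_path}: no DAGs found")

    counts: dict[str, int] = {}
    total: int | None = None
    with open(counts_path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith(TOTAL_DISEASES_KEY):
                    total = int(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{counts_path}: line {lineno}: expected "
                    f"'node_id<TAB>dag_count', got {line!r}"
                )
            counts[parts[0].strip()] = int(parts[1])
    if total is None:
        total = len(edges)
    return DiseaseDagSet(
        edges={d: tuple(e) for d, e in edges.items()},
        dag_counts=counts,
        total_diseases=total,
        delta=delta,
    )


def write_dag_set(
    dag_set: DiseaseDagSet,
    edges_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Write a DiseaseDagSet in the format :func:`read_dag_set` consumes."""
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for disease, edge_list in dag_set.edges.items():
            if not edge_list:
                writer.writerow([disease, "", ""])
            for parent, child in edge_list:
                writer.writerow([disease, parent, child])
    with open(counts_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {TOTAL_DISEASES_KEY}={dag_set.total_diseases}\n")
        for node, count in dag_set.dag_counts.items():
            fh.write(f"{node}\t{count}\n")


def write_matrix_tsv(
    values: np.ndarray,
    row_ids: tuple[str, ...],
    col_ids: tuple[str, ...],
    path: str | Path,
) -> None:
    """Dense matrix as TSV with a header row and an index column."""
    frame = pd.DataFrame(np.asarray(values), index=list(row_ids),
                         columns=list(col_ids))
    frame.to_csv(path, sep="\t", encoding="utf-8")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Read a dense TSV matrix written by :func:`write_matrix_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8",
                        comment="#")
    return (
        frame.to_numpy(dtype=float),
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
    )


def read_association_matrix_tsv(path: str | Path) -> AssociationMatrix:
    values, rows, cols = read_matrix_tsv(path)
    return AssociationMatrix(rows, cols, values)


def read_similarity_matrix_tsv(path: str | Path, name: str = "similarity") -> SimilarityMatrix:
    values, rows, cols = read_matrix_tsv(path)
    if rows != cols:
        raise ValidationError(f"{path}: row and column ids differ")
    return SimilarityMatrix(rows, values, name=name)


def ranked_predictions(
    S: ScoreMatrix | np.ndarray,
    A: AssociationMatrix,
    disease_id: str,
    top_n: int,
) -> pd.DataFrame:
    """Top candidate lncRNAs for one disease, known pairs excluded.

    Ties are broken by lexicographic lncRNA id so the ranking is
    deterministic. Returns a DataFrame with columns
    (rank, lncrna_id, disease_id, score, known).
    """
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    j = A.disease_index(disease_id)
    scores = S.values if isinstance(S, ScoreMatrix) else np.asarray(S)
    if scores.shape != A.values.shape:
        raise ValidationError("score matrix shape does not match associations")
    candidates = [
        (A.lncrna_ids[i], float(scores[i, j]))
        for i in range(A.n_lncrna)
        if A.values[i, j] == 0.0
    ]
    if not candidates:
        logger.warning(
            "disease %s: every lncRNA is already a known association; "
            "no candidates to rank", disease_id,
        )
    candidates.sort(key=lambda t: (-t[1], t[0]))
    rows = [
        {
            "rank": rank,
            "lncrna_id": lnc,
            "disease_id": disease_id,
            "score": score,
            "known": False,
        }
        for rank, (lnc, score) in enumerate(candidates[:top_n], start=1)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "lncrna_id", "disease_id", "score", "known"]
    )


def write_ranked_predictions(
    S: ScoreMatrix | np.ndarray,
    A: AssociationMatrix,
    disease_id: str,
    top_n: int,
    path: str | Path,
) -> pd.DataFrame:
    """Write :func:`ranked_predictions` output as TSV; returns the table."""
    table = ranked_predictions(S, A, disease_id, top_n)
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return table
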