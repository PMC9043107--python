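"""Cross-validated evaluation of the predictor.

Known associations are split into k near-equal folds. For each fold the
held-out positives are masked to zero in a training copy of the association
matrix and every association-dependent quantity — both GIP kernels, the
functional similarity, the integrations, the projections and the walk's
initial matrix — is recomputed from the training matrix, so no information
about the held-out pairs leaks into their scores. The fold's positives are
then ranked against the candidate pairs (pairs that are 0 in the original
matrix); training positives are excluded from the ranking. ROC curves sweep
all distinct score thresholds; AUC is the trapezoidal area, which gives ties
half credit (the midrank convention).

The per-run AUC is reported both pooled (all folds' test and candidate
scores concatenated) and as the mean of fold-level AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDagSet,
    ValidationError,
    WalkParams,
)
from .walk import predict

__all__ = ["kfold_split", "roc_auc", "run_cv", "grid_search",
           "CvReport", "GridResult"]


def kfold_split(A: AssociationMatrix, k: int, seed: int) -> dict[tuple[int, int], int]:
    """Randomly partition the positive pairs of ``A`` into k near-equal folds.

    Returns a map from (row, column) index pairs to fold labels 0..k-1.
    Fold sizes differ by at most one; the assignment is reproducible from
    ``seed``.
    """
    pairs = A.positive_pairs()
    n = len(pairs)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} known associations")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k  # first n % k folds get the extra pair
    rng.shuffle(labels)
    return {pair: int(lab) for pair, lab in zip(pairs, labels)}


def roc_auc(
    pos_scores: np.ndarray | list[float],
    neg_scores: np.ndarray | list[float],
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC for positive vs negative score sets.

    The curve is swept over all distinct scores as thresholds (predict
    positive when score >= threshold), anchored at (0, 0) and (1, 1).
    Trapezoidal integration makes tied scores contribute half credit, so the
    AUC equals the midrank Mann-Whitney statistic U / (n_pos * n_neg).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= t via binary search on the ascending sort
    tpr = (pos.size - np.searchsorted(pos_sorted, thresholds, "left")) / pos.size
    fpr = (neg.size - np.searchsorted(neg_sorted, thresholds, "left")) / neg.size
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class CvReport:
    """Result of one k-fold cross-validation run."""

    k: int
    seed: int
    fold_assignments: dict[tuple[int, int], int]
    per_fold_auc: list[float]
    pooled_auc: float
    mean_auc: float
    roc_points: np.ndarray  # pooled (fpr, tpr) pairs
    params: WalkParams

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation (seed {self.seed})",
            f"  walk: beta={self.params.beta} r1={self.params.r1} "
            f"r2={self.params.r2} mode={self.params.mode}",
            f"  pooled AUC : {self.pooled_auc:.4f}",
            f"  mean AUC   : {self.mean_auc:.4f}",
            "  fold AUCs  : "
            + " ".join(f"{a:.4f}" for a in self.per_fold_auc),
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the pooled ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points[:, 0], self.roc_points[:, 1],
                label=f"pooled AUC = {self.pooled_auc:.4f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax


def run_cv(
    A: AssociationMatrix,
    dag_set: DiseaseDagSet,
    params: WalkParams | None = None,
    k: int = 5,
    seed: int = 0,
    gamma_prime_l: float = 1.0,
    gamma_prime_d: float = 1.0,
    bandwidth_convention: str = "divide",
) -> CvReport:
    """k-fold cross-validation with per-fold recomputation of the pipeline."""
    params = params or WalkParams()
    folds = kfold_split(A, k, seed)
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    per_fold_auc: list[float] = []
    candidate_mask = A.values == 0.0
    for fold in range(k):
        test_pairs = [p for p, f in folds.items() if f == fold]
        train_values = A.values.copy()
        for i, j in test_pairs:
            train_values[i, j] = 0.0
        A_train = A.with_values(train_values)
        S = predict(
            A_train, dag_set, params,
            gamma_prime_l=gamma_prime_l,
            gamma_prime_d=gamma_prime_d,
            bandwidth_convention=bandwidth_convention,
        )
        pos = np.array([S.values[i, j] for i, j in test_pairs])
        neg = S.values[candidate_mask]
        _, fold_auc = roc_auc(pos, neg)
        per_fold_auc.append(fold_auc)
        pooled_pos.append(pos)
        pooled_neg.append(neg)
    roc_points, pooled_auc = roc_auc(
        np.concatenate(pooled_pos), np.concatenate(pooled_neg)
    )
    return CvReport(
        k=k,
        seed=seed,
        fold_assignments=folds,
        per_fold_auc=per_fold_auc,
        pooled_auc=pooled_auc,
        mean_auc=float(np.mean(per_fold_auc)),
        roc_points=roc_points,
        params=params,
    )


@dataclass
class GridResult:
    """All (beta, r1, r2, AUC) cells of a grid search plus the best cell."""

    rows: list[dict] = field(default_factory=list)

    @property
    def best(self) -> dict:
        return max(self.rows, key=lambda r: (r["auc"], -r["beta"],
                                             -r["r1"], -r["r2"]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows,
                            columns=["beta", "r1", "r2", "auc", "mean_auc"])


def grid_search(
    A: AssociationMatrix,
    dag_set: DiseaseDagSet,
    betas: list[float] | None = None,
    r_values: list[int] | None = None,
    k: int = 5,
    seed: int = 0,
    base_params: WalkParams | None = None,
    **cv_kwargs,
) -> GridResult:
    """Cross-validated grid search over beta and the two iteration caps.

    Defaults sweep beta over 0.1..0.9 in steps of 0.1 and r1, r2 over 1..5
    (225 cells). Every cell reuses the same seed, hence the same folds, so
    AUC differences reflect only the parameters.
    """
    if betas is None:
        betas = [round(0.1 * i, 1) for i in range(1, 10)]
    if r_values is None:
        r_values = [1, 2, 3, 4, 5]
    if not betas or not r_values:
        raise ValidationError("grid search needs non-empty parameter lists")
    base = base_params or WalkParams()
    result = GridResult()
    for beta in betas:
        for r1 in r_values:
            for r2 in r_values:
                params = WalkParams(
                    beta=beta, r1=r1, r2=r2,
                    normalization_variant=base.normalization_variant,
                    mode=base.mode,
                    exhausted_policy=base.exhausted_policy,
                )
                report = run_cv(A, dag_set, params, k=k, seed=seed,
                                **cv_kwargs)
                result.rows.append({
                    "beta": beta, "r1": r1, "r2": r2,
                    "auc": report.pooled_auc,
                    "mean_auc": report.mean_auc,
                })
    return result
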