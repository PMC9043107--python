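"""Model-level API: build a predictor from data, fit it, inspect results.

The :class:`NCPBiRW` class bundles an association matrix, a disease DAG set
and the algorithm parameters; :meth:`NCPBiRW.fit` runs the full pipeline
(similarity kernels, integration, network-consistency projection, bi-random
walk) and returns an :class:`NCPBiRWResults` object carrying the final score
matrix, every intermediate matrix and a text ``summary()``. Cross-validation
and the parameter grid search are methods of the model, so the same object
that predicts also evaluates itself.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .containers import (
    AssociationMatrix,
    DiseaseDagSet,
    ProjectionScores,
    ScoreMatrix,
    SimilarityMatrix,
    WalkParams,
)
from .data_io import (
    ranked_predictions,
    read_association_list,
    read_dag_set,
    write_matrix_tsv,
)
from .evaluation import CvReport, GridResult, grid_search, run_cv
from .projection import disease_projection, lncrna_projection
from .similarity import (
    disease_semantic_similarity,
    gip_kernel,
    integrate_disease,
    integrate_lncrna,
    lncrna_functional_similarity,
)
from .walk import birw_scores, normalize_similarity

__all__ = ["NCPBiRW", "NCPBiRWResults"]


class NCPBiRW:
    """Network-consistency-projection bi-random-walk association predictor.

    Parameters
    ----------
    associations : binary lncRNA x disease incidence matrix.
    dags : per-disease ancestor DAGs with membership counts, driving the
        semantic similarity; diseases missing from it fall back to the GIP
        kernel alone.
    beta : decay factor in [0, 1] balancing network diffusion (beta) against
        the projection restart term (1 - beta). Default 0.8.
    r1, r2 : iteration caps on the lncRNA and disease similarity networks.
        Default 1 each.
    gamma_prime_l, gamma_prime_d : GIP bandwidth scale factors, default 1.
    mode : "full", "ncp_only" (projection scores only) or "birw_only"
        (plain bi-random walk without projection).
    normalization_variant : "literal" row-sum*column-sum product
        normalization or its "sqrt" symmetric variant.
    """

    def __init__(
        self,
        associations: AssociationMatrix,
        dags: DiseaseDagSet,
        beta: float = 0.8,
        r1: int = 1,
        r2: int = 1,
        gamma_prime_l: float = 1.0,
        gamma_prime_d: float = 1.0,
        mode: str = "full",
        normalization_variant: str = "literal",
        exhausted_policy: str = "freeze",
        bandwidth_convention: str = "divide",
    ) -> None:
        self.associations = associations
        self.dags = dags
        self.params = WalkParams(
            beta=beta, r1=r1, r2=r2,
            normalization_variant=normalization_variant,
            mode=mode, exhausted_policy=exhausted_policy,
        )
        self.gamma_prime_l = gamma_prime_l
        self.gamma_prime_d = gamma_prime_d
        self.bandwidth_convention = bandwidth_convention

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def from_files(
        cls,
        associations: str | Path,
        dag_edges: str | Path,
        dag_counts: str | Path,
        delta: float = 0.5,
        header: bool = False,
        **params,
    ) -> "NCPBiRW":
        """Build a model from an edge-list TSV and the two DAG TSV files."""
        A = read_association_list(associations, header=header)
        dag_set = read_dag_set(dag_edges, dag_counts, delta=delta)
        return cls(A, dag_set, **params)

    @classmethod
    def from_frame(
        cls,
        edges: pd.DataFrame,
        dags: DiseaseDagSet,
        lncrna_col: str = "lncrna_id",
        disease_col: str = "disease_id",
        **params,
    ) -> "NCPBiRW":
        """Build a model from a two-column pandas edge DataFrame."""
        lnc_order: dict[str, int] = {}
        dis_order: dict[str, int] = {}
        pairs = set()
        for lnc, dis in zip(edges[lncrna_col], edges[disease_col]):
            lnc_order.setdefault(str(lnc), len(lnc_order))
            dis_order.setdefault(str(dis), len(dis_order))
            pairs.add((str(lnc), str(dis)))
        values = np.zeros((len(lnc_order), len(dis_order)))
        for lnc, dis in pairs:
            values[lnc_order[lnc], dis_order[dis]] = 1.0
        A = AssociationMatrix(tuple(lnc_order), tuple(dis_order), values)
        return cls(A, dags, **params)

    # ------------------------------------------------------------------
    def fit(self) -> "NCPBiRWResults":
        """Run the full scoring pipeline; deterministic given the inputs."""
        A = self.associations
        KL = gip_kernel(A, "lncrna", self.gamma_prime_l,
                        self.bandwidth_convention)
        KD = gip_kernel(A, "disease", self.gamma_prime_d,
                        self.bandwidth_convention)
        SV = disease_semantic_similarity(self.dags, A.disease_ids)
        FL = lncrna_functional_similarity(A, SV)
        LS = integrate_lncrna(KL, FL)
        DS = integrate_disease(KD, SV)
        lsncp = lncrna_projection(LS, A)
        dsncp = disease_projection(DS, A)
        NLS = normalize_similarity(LS, self.params.normalization_variant)
        NDS = normalize_similarity(DS, self.params.normalization_variant)
        scores = birw_scores(NLS, NDS, A, lsncp, dsncp, self.params)
        return NCPBiRWResults(
            model=self, scores=scores, KL=KL, KD=KD, SV=SV, FL=FL,
            LS=LS, DS=DS, lsncp=lsncp, dsncp=dsncp,
        )

    def cross_validate(self, k: int = 5, seed: int = 0) -> CvReport:
        """k-fold CV with per-fold recomputation of the whole pipeline."""
        return run_cv(
            self.associations, self.dags, self.params, k=k, seed=seed,
            gamma_prime_l=self.gamma_prime_l,
            gamma_prime_d=self.gamma_prime_d,
            bandwidth_convention=self.bandwidth_convention,
        )

    def grid_search(
        self,
        betas: list[float] | None = None,
        r_values: list[int] | None = None,
        k: int = 5,
        seed: int = 0,
    ) -> GridResult:
        """Cross-validated sweep over beta and the iteration caps."""
        return grid_search(
            self.associations, self.dags, betas=betas, r_values=r_values,
            k=k, seed=seed, base_params=self.params,
            gamma_prime_l=self.gamma_prime_l,
            gamma_prime_d=self.gamma_prime_d,
            bandwidth_convention=self.bandwidth_convention,
        )


class NCPBiRWResults:
    """Fitted scores plus every intermediate matrix of the pipeline."""

    def __init__(
        self,
        model: NCPBiRW,
        scores: ScoreMatrix,
        KL: SimilarityMatrix,
        KD: SimilarityMatrix,
        SV: SimilarityMatrix,
        FL: SimilarityMatrix,
        LS: SimilarityMatrix,
        DS: SimilarityMatrix,
        lsncp: ProjectionScores,
        dsncp: ProjectionScores,
    ) -> None:
        self.model = model
        self.scores = scores
        self.KL, self.KD, self.SV, self.FL = KL, KD, SV, FL
        self.LS, self.DS = LS, DS
        self.lsncp, self.dsncp = lsncp, dsncp

    def scores_frame(self) -> pd.DataFrame:
        """Final scores as a lncRNA x disease DataFrame."""
        return pd.DataFrame(
            self.scores.values,
            index=list(self.scores.lncrna_ids),
            columns=list(self.scores.disease_ids),
        )

    def top_predictions(self, disease_id: str, n: int = 10) -> pd.DataFrame:
        """Top-n novel candidate lncRNAs for one disease (known excluded)."""
        return ranked_predictions(self.scores, self.model.associations,
                                  disease_id, n)

    def save_scores(self, path: str | Path) -> None:
        write_matrix_tsv(self.scores.values, self.scores.lncrna_ids,
                         self.scores.disease_ids, path)

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        A = self.model.associations
        p = self.model.params
        density = A.n_associations / (A.n_lncrna * A.n_disease)
        s = self.scores.values
        lines = [
            "NCP-BiRW association prediction".center(58),
            "=" * 58,
            f"{'lncRNAs:':<28}{A.n_lncrna:>10}",
            f"{'diseases:':<28}{A.n_disease:>10}",
            f"{'known associations:':<28}{A.n_associations:>10}",
            f"{'matrix density:':<28}{density:>10.4f}",
            f"{'diseases with a DAG:':<28}"
            f"{sum(d in self.model.dags for d in A.disease_ids):>10}",
            "-" * 58,
            f"{'mode:':<28}{p.mode:>10}",
            f"{'decay factor beta:':<28}{p.beta:>10.2f}",
            f"{'iteration caps r1, r2:':<28}{f'{p.r1}, {p.r2}':>10}",
            f"{'normalization:':<28}{p.normalization_variant:>10}",
            f"{'GIP gamma-prime (l, d):':<28}"
            f"{f'{self.model.gamma_prime_l:g}, {self.model.gamma_prime_d:g}':>10}",
            "-" * 58,
            f"{'score min / max:':<28}{s.min():>10.3e} / {s.max():.3e}",
            f"{'score grand total:':<28}{s.sum():>10.4f}",
            "=" * 58,
            f"ncpbirw {_version}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        A = self.model.associations
        return (f"<NCPBiRWResults {A.n_lncrna}x{A.n_disease}, "
                f"mode={self.model.params.mode}>")
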