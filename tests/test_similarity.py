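"""Similarity kernels against hand-derived values and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ncpbirw.containers import (
    AssociationMatrix,
    DiseaseDagSet,
    ValidationError,
)
from ncpbirw.similarity import (
    disease_semantic_similarity,
    gip_kernel,
    integrate_disease,
    integrate_lncrna,
    lncrna_functional_similarity,
    semantic_contribution,
    semantic_value,
)

from conftest import random_association, random_dag_forest


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def gip_oracle(profiles: np.ndarray, gamma_prime: float) -> np.ndarray:
    n = profiles.shape[0]
    mean_sq = sum(float(p @ p) for p in profiles) / n
    if mean_sq == 0:
        return np.eye(n)
    gamma = gamma_prime / mean_sq
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            out[i, j] = math.exp(-gamma * float(diff @ diff))
    return out


def semantic_oracle(ds: DiseaseDagSet, d: str) -> dict[str, float]:
    """Recursive contribution computation straight from the definition."""
    members = ds.ancestor_set(d)
    max_count = max(ds.dag_counts.values())

    def dd(s: str) -> float:
        if s == d:
            return 1.0
        kids = [c for p, c in ds.edges[d] if p == s and c in members]
        p_s = (max_count - ds.dag_counts[s]) / ds.total_diseases
        return max((ds.delta + p_s) * dd(c) for c in kids)

    return {s: dd(s) for s in members}


def sv_oracle(ds: DiseaseDagSet, di: str, dj: str) -> float:
    ci, cj = semantic_oracle(ds, di), semantic_oracle(ds, dj)
    shared = set(ci) & set(cj)
    if not shared:
        return 0.0
    return sum(ci[s] + cj[s] for s in shared) / (
        sum(ci.values()) + sum(cj.values())
    )


def fl_oracle(A: AssociationMatrix, SV: np.ndarray) -> np.ndarray:
    nl = A.n_lncrna
    sets = [list(np.nonzero(A.values[i])[0]) for i in range(nl)]
    out = np.zeros((nl, nl))
    for i in range(nl):
        for j in range(nl):
            Di, Dj = sets[i], sets[j]
            if not Di or not Dj:
                continue
            s_ij = sum(max(SV[d, dp] for dp in Dj) for d in Di)
            s_ji = sum(max(SV[d, dp] for dp in Di) for d in Dj)
            out[i, j] = (s_ij + s_ji) / (len(Di) + len(Dj))
    return out


# ---------------------------------------------------------------------------
# GIP kernel

class TestGipKernel:
    def test_identity_profiles_hand_value(self, identity_assoc):
        """Orthogonal unit profiles: bandwidth 1, off-diagonal exp(-2)."""
        K = gip_kernel(identity_assoc, "lncrna", 1.0)
        np.testing.assert_allclose(np.diag(K.values), 1.0, atol=1e-12)
        assert K.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-9)

    def test_identical_profiles_score_one(self):
        A = AssociationMatrix(("a", "b"), ("x", "y"),
                              np.array([[1.0, 0.0], [1.0, 0.0]]))
        K = gip_kernel(A, "lncrna")
        assert K.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_all_ones_disease_side(self):
        A = AssociationMatrix(("a", "b"), ("x", "y"), np.ones((2, 2)))
        K = gip_kernel(A, "disease")
        np.testing.assert_allclose(K.values, 1.0, atol=1e-12)

    def test_invalid_gamma_prime(self, identity_assoc):
        with pytest.raises(ValidationError):
            gip_kernel(identity_assoc, "lncrna", 0.0)

    def test_multiplicative_convention_switch(self, identity_assoc):
        K = gip_kernel(identity_assoc, "lncrna", 2.0,
                       bandwidth_convention="multiply")
        # mean squared norm 1 -> gamma = 2, off-diagonal exp(-4)
        assert K.values[0, 1] == pytest.approx(math.exp(-4.0), abs=1e-12)

    @pytest.mark.parametrize("side", ["lncrna", "disease"])
    def test_oracle_agreement_random_instances(self, side):
        rng = np.random.default_rng(42)
        for _ in range(100):
            A = random_association(rng, 6, 4)
            profiles = A.values if side == "lncrna" else A.values.T
            expected = gip_oracle(profiles, 1.0)
            got = gip_kernel(A, side).values
            np.testing.assert_allclose(got, expected, atol=1e-12)


def test_all_zero_profiles_return_identity(caplog):
    A = AssociationMatrix(("a", "b"), ("x",), np.zeros((2, 1)))
    K = gip_kernel(A, "lncrna")
    np.testing.assert_array_equal(K.values, np.eye(2))


# ---------------------------------------------------------------------------
# semantic similarity

class TestSemanticContribution:
    def test_disease_contributes_one_to_itself(self, two_node_dagset):
        assert semantic_contribution(two_node_dagset, "d2")["d2"] == 1.0

    def test_two_node_fixture(self, two_node_dagset):
        """dags(d1)=2 is the vocabulary max, so its rarity bonus is 0 and
        the parent contributes delta * 1 = 0.5."""
        c = semantic_contribution(two_node_dagset, "d2")
        assert c["d1"] == pytest.approx(0.5, abs=1e-12)
        assert semantic_value(two_node_dagset, "d2") == pytest.approx(1.5)

    def test_rare_ancestor_gets_frequency_bonus(self):
        """With dags(d1)=1 against a vocabulary max of 2, the bonus
        (2-1)/2 = 0.5 lifts the parent contribution to exactly 1."""
        ds = DiseaseDagSet(
            edges={"d1": (), "d2": (("d1", "d2"),)},
            dag_counts={"d1": 1, "d2": 2},
            total_diseases=2,
        )
        c = semantic_contribution(ds, "d2")
        assert c["d1"] == pytest.approx(1.0, abs=1e-12)

    def test_three_node_chain_decay(self):
        """All counts equal: pure delta decay, DV = 1 + 0.5 + 0.25."""
        ds = DiseaseDagSet(
            edges={"a": (), "b": (("a", "b"),),
                   "c": (("a", "b"), ("b", "c"))},
            dag_counts={"a": 3, "b": 3, "c": 3},
            total_diseases=3,
        )
        assert semantic_value(ds, "c") == pytest.approx(1.75, abs=1e-12)

    def test_singleton_semantic_value_is_one(self):
        ds = DiseaseDagSet(edges={"d": ()}, dag_counts={"d": 1},
                           total_diseases=1)
        assert semantic_value(ds, "d") == 1.0


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, two_node_dagset):
        SV = disease_semantic_similarity(two_node_dagset, ("d1", "d2"))
        np.testing.assert_allclose(np.diag(SV.values), 1.0, atol=1e-12)

    def test_two_node_fixture_value(self, two_node_dagset):
        SV = disease_semantic_similarity(two_node_dagset, ("d1", "d2"))
        assert SV.values[0, 1] == pytest.approx(0.6, abs=1e-9)

    def test_disjoint_dags_score_zero(self):
        ds = DiseaseDagSet(edges={"a": (), "b": ()},
                           dag_counts={"a": 1, "b": 1}, total_diseases=2)
        SV = disease_semantic_similarity(ds, ("a", "b"))
        assert SV.values[0, 1] == 0.0

    def test_missing_dag_gets_zero_row(self, two_node_dagset, caplog):
        SV = disease_semantic_similarity(two_node_dagset,
                                         ("d1", "d2", "orphan"))
        assert SV.values[2, 2] == 1.0
        assert SV.values[2, 0] == SV.values[2, 1] == 0.0

    def test_oracle_agreement_random_forests(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            ds = random_dag_forest(rng, n)
            diseases = ds.diseases
            SV = disease_semantic_similarity(ds, diseases).values
            for i in range(n):
                for j in range(n):
                    expected = (1.0 if i == j
                                else sv_oracle(ds, diseases[i], diseases[j]))
                    assert SV[i, j] == pytest.approx(expected, abs=1e-12)

    def test_shared_ancestor_never_decreases_similarity(self):
        """Grafting a common root above both DAGs adds a shared term to the
        numerator and can only raise the ratio from 0."""
        base = DiseaseDagSet(edges={"a": (), "b": ()},
                             dag_counts={"a": 1, "b": 1}, total_diseases=2)
        grafted = DiseaseDagSet(
            edges={"a": (("r", "a"),), "b": (("r", "b"),)},
            dag_counts={"a": 1, "b": 1, "r": 2},
            total_diseases=2,
        )
        sv0 = disease_semantic_similarity(base, ("a", "b")).values[0, 1]
        sv1 = disease_semantic_similarity(grafted, ("a", "b")).values[0, 1]
        assert sv1 >= sv0


# ---------------------------------------------------------------------------
# functional similarity and integration

class TestFunctionalSimilarity:
    def _sv(self, ids, values):
        from ncpbirw.containers import SimilarityMatrix
        return SimilarityMatrix(ids, np.asarray(values, dtype=float),
                                name="SV")

    def test_single_disease_pair_hand_value(self):
        A = AssociationMatrix(("l1", "l2"), ("d1", "d2"), np.eye(2))
        SV = self._sv(("d1", "d2"), [[1.0, 0.6], [0.6, 1.0]])
        FL = lncrna_functional_similarity(A, SV)
        assert FL.values[0, 1] == pytest.approx(0.6, abs=1e-9)
        np.testing.assert_allclose(np.diag(FL.values), 1.0)

    def test_identical_disease_sets_score_one(self):
        A = AssociationMatrix(("l1", "l2"), ("d1", "d2"),
                              np.array([[1.0, 1.0], [1.0, 1.0]]))
        SV = self._sv(("d1", "d2"), [[1.0, 0.3], [0.3, 1.0]])
        FL = lncrna_functional_similarity(A, SV)
        assert FL.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_empty_disease_set_scores_zero(self):
        A = AssociationMatrix(("l1", "l2"), ("d1",),
                              np.array([[1.0], [0.0]]))
        SV = self._sv(("d1",), [[1.0]])
        FL = lncrna_functional_similarity(A, SV)
        assert FL.values[0, 1] == 0.0
        assert FL.values[1, 1] == 0.0  # empty row: diagonal also 0

    def test_index_mismatch_rejected(self):
        A = AssociationMatrix(("l1",), ("d1",), np.ones((1, 1)))
        SV = self._sv(("other",), [[1.0]])
        with pytest.raises(ValidationError):
            lncrna_functional_similarity(A, SV)

    def test_oracle_agreement_random_instances(self):
        rng = np.random.default_rng(9)
        from ncpbirw.containers import SimilarityMatrix
        for _ in range(100):
            A = random_association(rng, 6, 5)
            sv_raw = rng.random((5, 5))
            sv_raw = 0.5 * (sv_raw + sv_raw.T)
            np.fill_diagonal(sv_raw, 1.0)
            SV = SimilarityMatrix(A.disease_ids, sv_raw, name="SV")
            expected = fl_oracle(A, sv_raw)
            # the definition forces the diagonal to 1 for non-empty rows;
            # the naive oracle reproduces that analytically already
            got = lncrna_functional_similarity(A, SV).values
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestIntegration:
    def _sim(self, values, name="m"):
        from ncpbirw.containers import SimilarityMatrix
        n = len(values)
        return SimilarityMatrix(tuple(f"e{i}" for i in range(n)),
                                np.asarray(values, dtype=float), name=name)

    def test_mean_where_informative(self):
        KL = self._sim([[1.0, 0.4], [0.4, 1.0]])
        FL = self._sim([[1.0, 0.6], [0.6, 1.0]])
        LS = integrate_lncrna(KL, FL)
        assert LS.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_fallback_to_kernel_where_zero(self):
        KD = self._sim([[1.0, 0.8], [0.8, 1.0]])
        SV = self._sim([[1.0, 0.0], [0.0, 1.0]])
        DS = integrate_disease(KD, SV)
        assert DS.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_equal_matrices_are_fixed_point(self):
        K = self._sim([[1.0, 0.3], [0.3, 1.0]])
        LS = integrate_lncrna(K, K)
        np.testing.assert_allclose(LS.values, K.values, atol=1e-12)
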