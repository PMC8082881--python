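import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smalf.core_data import AssociationDataset
from smalf.similarity import (
    DiseaseDAG,
    SimilarityMatrix,
    disease_semantic_similarity,
    disease_similarity_matrix,
    mirna_functional_similarity,
    mirna_similarity_matrix,
    semantic_contributions,
)
from conftest import random_dag


def enumerate_contributions(dag: DiseaseDAG, focus: str, delta: float) -> dict:
    """Independent oracle: contribution of d = max over all downward paths
    d -> ... -> focus of delta ** path_length."""
    g = dag.graph
    out = {}
    for d in dag.ancestor_closure(focus):
        best = None
        for path in nx.all_simple_paths(g, d, focus):
            val = delta ** (len(path) - 1)
            best = val if best is None else max(best, val)
        if d == focus:
            best = 1.0
        out[d] = best
    return out


class TestSemanticContributions:
    def test_isolated_term_contributes_one(self):
        dag = DiseaseDAG.from_edges([], terms=["D"])
        cm = semantic_contributions(dag, "D")
        assert cm.contributions == {"D": 1.0}
        assert cm.semantic_value == 1.0

    def test_chain_decays_per_step(self, chain_dag):
        cm = semantic_contributions(chain_dag, "D", delta=0.5)
        assert cm.contributions == {"D": 1.0, "C": 0.5, "R": 0.25}
        assert cm.semantic_value == pytest.approx(1.75)

    def test_diamond_takes_max_over_children(self, diamond_dag):
        cm = semantic_contributions(diamond_dag, "D", delta=0.5)
        assert cm.contributions == {"D": 1.0, "A": 0.5, "B": 0.5, "R": 0.25}
        assert cm.semantic_value == pytest.approx(2.25)

    def test_missing_term_errors(self, chain_dag):
        with pytest.raises(KeyError):
            semantic_contributions(chain_dag, "nope")

    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG.from_edges([("A", "B"), ("B", "A")])

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("delta", [0.3, 0.5, 0.7])
    def test_agrees_with_path_enumeration_oracle(self, seed, delta):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, n_nodes=int(rng.integers(4, 13)))
        focus = f"n{rng.integers(len(dag.terms))}"
        cm = semantic_contributions(dag, focus, delta)
        oracle = enumerate_contributions(dag, focus, delta)
        assert set(cm.contributions) == set(oracle)
        for term, expected in oracle.items():
            assert cm.contributions[term] == pytest.approx(expected, abs=1e-12)
        assert cm.semantic_value == pytest.approx(sum(oracle.values()), abs=1e-12)


class TestContributionProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), delta=st.floats(0.05, 0.95))
    def test_contributions_bounded_and_match_oracle(self, seed, delta):
        """On arbitrary random DAGs, every contribution is a power of delta
        in (0, 1], the focus contributes 1, DV >= 1, and the recursion agrees
        with exhaustive path enumeration."""
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(2, 10)))
        focus = f"n{rng.integers(len(dag.terms))}"
        cm = semantic_contributions(dag, focus, delta)
        assert cm.contributions[focus] == 1.0
        assert cm.semantic_value >= 1.0
        oracle = enumerate_contributions(dag, focus, delta)
        for term, value in cm.contributions.items():
            assert 0.0 < value <= 1.0
            assert value == pytest.approx(oracle[term], abs=1e-12)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, diamond_dag):
        for t in ("D", "A", "R"):
            assert disease_semantic_similarity(diamond_dag, t, t) == pytest.approx(1.0)

    def test_disjoint_components_share_nothing(self):
        dag = DiseaseDAG.from_edges([("R1", "A"), ("R2", "B")])
        assert disease_semantic_similarity(dag, "A", "B") == 0.0

    def test_siblings_under_root(self, sibling_dag):
        assert disease_semantic_similarity(sibling_dag, "A", "B", delta=0.5) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(100 + seed)
        dag = random_dag(rng, 10)
        terms = sorted(dag.terms)
        for a, b in itertools.combinations(terms, 2):
            s_ab = disease_semantic_similarity(dag, a, b)
            s_ba = disease_semantic_similarity(dag, b, a)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert 0.0 <= s_ab <= 1.0

    def test_larger_delta_weakly_increases_similarity(self, chain_dag, diamond_dag):
        for dag, a, b in [(diamond_dag, "A", "B"), (chain_dag, "C", "D")]:
            sims = [
                disease_semantic_similarity(dag, a, b, delta=d) for d in (0.3, 0.5, 0.7)
            ]
            assert sims[0] <= sims[1] + 1e-12 <= sims[2] + 2e-12

    def test_shared_ancestor_does_not_decrease_similarity(self):
        # two roots joined only through a new common parent raise SS from 0
        separate = DiseaseDAG.from_edges([("R1", "A"), ("R2", "B")])
        joined = DiseaseDAG.from_edges([("T", "R1"), ("T", "R2"), ("R1", "A"), ("R2", "B")])
        assert disease_semantic_similarity(joined, "A", "B") >= disease_semantic_similarity(
            separate, "A", "B"
        ) - 1e-12


class TestDiseaseSimilarityMatrix:
    def test_single_disease(self, sibling_dag):
        sm = disease_similarity_matrix(sibling_dag, ["A"])
        assert sm.values.tolist() == [[1.0]]

    def test_sibling_matrix_values(self, sibling_dag):
        sm = disease_similarity_matrix(sibling_dag, ["A", "B"])
        np.testing.assert_allclose(sm.values, [[1, 1 / 3], [1 / 3, 1]])

    def test_empty_list_errors(self, sibling_dag):
        with pytest.raises(ValueError, match="empty"):
            disease_similarity_matrix(sibling_dag, [])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        dag = random_dag(rng, 9)
        ids = sorted(dag.terms)
        sm = disease_similarity_matrix(dag, ids)
        perm = list(rng.permutation(len(ids)))
        sm_p = disease_similarity_matrix(dag, [ids[i] for i in perm])
        np.testing.assert_array_equal(sm.values[np.ix_(perm, perm)], sm_p.values)

    def test_unmapped_disease_gets_missing_markers(self, sibling_dag):
        dag = DiseaseDAG(sibling_dag.graph, {"A": ("A",), "B": ("B",)})
        sm = disease_similarity_matrix(dag, ["A", "B", "unknown"])
        assert sm.values[2, 2] == 1.0
        assert np.isnan(sm.values[0, 2]) and np.isnan(sm.values[2, 1])

    def test_multi_term_annotation_takes_max(self, diamond_dag):
        # disease X maps to both A and B; similarity to a disease on A should
        # equal the best of SS(A,A), SS(B,A)
        dag = DiseaseDAG(diamond_dag.graph, {"X": ("A", "B"), "YA": ("A",)})
        sm = disease_similarity_matrix(dag, ["X", "YA"])
        expected = max(
            disease_semantic_similarity(diamond_dag, a, "A") for a in ("A", "B")
        )
        assert sm.values[0, 1] == pytest.approx(expected)

    def test_round_trip_csv_preserves_missing(self, tmp_path, sibling_dag):
        dag = DiseaseDAG(sibling_dag.graph, {"A": ("A",)})
        sm = disease_similarity_matrix(dag, ["A", "zzz"])
        f = tmp_path / "ss.csv"
        sm.to_csv(f)
        back = SimilarityMatrix.from_csv(f)
        assert back.ids == sm.ids
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(sm.values))
        np.testing.assert_allclose(back.values[0, 0], 1.0)


class TestMirnaFunctionalSimilarity:
    def ss(self):
        # SS over diseases {A, B} with SS(A,B)=1/3 (the sibling toy DAG)
        return SimilarityMatrix(("A", "B"), np.array([[1.0, 1 / 3], [1 / 3, 1.0]]))

    def test_identical_singleton_sets(self):
        ds = AssociationDataset(("m1", "m2"), ("A", "B"), np.array([[1, 0], [1, 0]]))
        assert mirna_functional_similarity(ds, self.ss(), 0, 1) == pytest.approx(1.0)

    def test_disjoint_singleton_sets(self):
        ds = AssociationDataset(("m1", "m2"), ("A", "B"), np.array([[1, 0], [0, 1]]))
        assert mirna_functional_similarity(ds, self.ss(), 0, 1) == pytest.approx(1 / 3)

    def test_two_versus_one_disease_bma(self):
        ds = AssociationDataset(("m1", "m2"), ("A", "B"), np.array([[1, 1], [1, 0]]))
        # BMA = [best(A,{A}) + best(B,{A}) + best(A,{A,B})] / 3 = (1 + 1/3 + 1)/3
        assert mirna_functional_similarity(ds, self.ss(), 0, 1) == pytest.approx(7 / 9)

    def test_empty_disease_set_yields_missing(self):
        ds = AssociationDataset(("m1", "m2"), ("A", "B"), np.array([[1, 0], [0, 0]]))
        assert np.isnan(mirna_functional_similarity(ds, self.ss(), 0, 1))

    def test_matrix_symmetric_unit_diagonal(self, toy_dataset, sibling_dag):
        SS = disease_similarity_matrix(sibling_dag, list(toy_dataset.disease_ids))
        FS = mirna_similarity_matrix(toy_dataset, SS)
        np.testing.assert_allclose(np.diag(FS.values), 1.0)
        np.testing.assert_allclose(FS.values, FS.values.T)
        finite = np.isfinite(FS.values)
        assert ((FS.values[finite] >= 0) & (FS.values[finite] <= 1)).all()
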