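"""The five base similarity models against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mspcd.dataio import AssociationMatrix, DiseaseDAG, SequenceSet
from mspcd.errors import CoverageError, ParameterError
from mspcd.similarity import (
    EditCosts,
    GipParams,
    SemanticParams,
    circ_gip_similarity,
    disease_gip_similarity,
    functional_similarity,
    gip_bandwidth,
    gip_kernel,
    jaccard,
    levenshtein_distance,
    semantic_contribution,
    semantic_similarity_1,
    semantic_similarity_2,
    sequence_similarity,
    sequence_similarity_matrix,
)

from conftest import random_association


def lcs_length(a: str, b: str) -> int:
    """Independent longest-common-subsequence dynamic program."""
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b):
            cur.append(prev[j] + 1 if ca == cb else max(prev[j + 1], cur[-1]))
        prev = cur
    return prev[-1]


dna = st.text(alphabet="ACGT", max_size=12)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("A", "G", 2),  # one substitution at cost 2
            ("ACGT", "ACG", 1),  # one deletion
            ("", "ACG", 3),
            ("AC", "", 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein_distance(a, b) == expected

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(dna, dna)
    def test_equals_lcs_identity_under_default_costs(self, a, b):
        # with costs (1,1,2): distance = l(a)+l(b) - 2*LCS(a,b)
        assert levenshtein_distance(a, b) == len(a) + len(b) - 2 * lcs_length(a, b)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        assert levenshtein_distance(a, b) == levenshtein_distance(b, a)

    def test_asymmetric_costs(self):
        costs = EditCosts(insert=3.0, delete=1.0, substitute=10.0)
        # 'A' -> 'AG': cheapest is one insert (3), not delete+2 inserts
        assert levenshtein_distance("A", "AG", costs) == 3.0

    def test_negative_costs_rejected(self):
        with pytest.raises(ParameterError):
            EditCosts(insert=-1.0)


class TestSequenceSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 1.0), ("A", "G", 0.0), ("ACGT", "ACG", 6 / 7)],
    )
    def test_known_scores(self, a, b, expected):
        assert sequence_similarity(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=10),
           st.text(alphabet="ACGT", min_size=1, max_size=10))
    def test_bounds_symmetry_and_identity(self, a, b):
        s = sequence_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == sequence_similarity(b, a)
        assert (s == 1.0) == (a == b)

    def test_both_empty_rejected(self):
        with pytest.raises(ParameterError):
            sequence_similarity("", "")

    def test_matrix_matches_pairwise_calls(self, rng):
        ids = [f"c{i}" for i in range(6)]
        seqs = SequenceSet(
            {i: "".join(rng.choice(list("ACGT"), size=15)) for i in ids}
        )
        m = sequence_similarity_matrix(seqs, ids)
        for i, j in itertools.combinations(range(6), 2):
            expected = sequence_similarity(seqs.sequences[ids[i]], seqs.sequences[ids[j]])
            assert m.values[i, j] == pytest.approx(expected)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_missing_sequence_gets_placeholder_zero(self):
        seqs = SequenceSet({"c1": "ACGT", "c2": "ACGT"})
        m = sequence_similarity_matrix(seqs, ["c1", "c2", "c3"])
        assert m.values[0, 1] == 1.0
        assert m.values[0, 2] == 0.0 and m.values[2, 2] == 0.0


class TestJaccard:
    def test_exhaustive_against_set_oracle(self):
        universe = range(6)
        for bits_u in itertools.product([0, 1], repeat=6):
            for bits_v in itertools.product([0, 1], repeat=6):
                su = {i for i in universe if bits_u[i]}
                sv = {i for i in universe if bits_v[i]}
                expected = len(su & sv) / len(su | sv) if su | sv else 0.0
                assert jaccard(np.array(bits_u), np.array(bits_v)) == pytest.approx(
                    expected
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            jaccard(np.array([1, 0]), np.array([1, 0, 1]))


class TestFunctionalSimilarity:
    def test_matches_mean_of_set_jaccards(self, rng):
        n = 5
        mats = []
        for n_cols in (4, 6, 3):
            mats.append(random_association(rng, n_rows=n, n_cols=n_cols, p=0.5))
        # force identical circRNA ids
        for m in mats:
            m.row_ids = [f"c{i}" for i in range(n)]
        cf = functional_similarity(*mats)
        for i, j in itertools.combinations_with_replacement(range(n), 2):
            parts = []
            for m in mats:
                a = set(np.flatnonzero(m.values[i]))
                b = set(np.flatnonzero(m.values[j]))
                parts.append(len(a & b) / len(a | b) if a | b else 0.0)
            assert cf.values[i, j] == pytest.approx(np.mean(parts))

    def test_component_average_forced(self):
        # component Jaccards (1, 0, 0.5) average to 0.5
        Sd = AssociationMatrix(np.array([[1, 0], [1, 0]]), ["a", "b"], ["d1", "d2"])
        Sg = AssociationMatrix(np.array([[1, 0], [0, 1]]), ["a", "b"], ["g1", "g2"])
        Sm = AssociationMatrix(np.array([[1, 1], [1, 0]]), ["a", "b"], ["m1", "m2"])
        cf = functional_similarity(Sd, Sg, Sm)
        assert cf.values[0, 1] == pytest.approx(0.5)


class TestGipKernel:
    def test_bandwidth_on_identity_profiles(self):
        profiles = np.eye(2)
        assert gip_bandwidth(profiles) == pytest.approx(1.0)
        assert gip_bandwidth(profiles, GipParams("reciprocal")) == pytest.approx(1.0)

    def test_all_zero_profiles_degenerate(self):
        with pytest.raises(ParameterError):
            gip_bandwidth(np.zeros((3, 4)))

    def test_hand_evaluated_kernel(self):
        m = gip_kernel(np.eye(2), ["a", "b"])
        assert m.values[0, 0] == 1.0
        assert m.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_identical_rows_score_one(self, rng):
        profiles = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        m = gip_kernel(profiles, list("abc"))
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_psd_unit_diagonal_on_random_profiles(self, rng):
        for _ in range(5):
            profiles = (rng.random((20, 12)) < 0.3).astype(float)
            if profiles.sum() == 0:
                continue
            m = gip_kernel(profiles, [f"x{i}" for i in range(20)])
            assert np.allclose(np.diag(m.values), 1.0)
            assert np.allclose(m.values, m.values.T)
            assert np.linalg.eigvalsh(m.values).min() >= -1e-8

    def test_profile_orientation(self, worked_example):
        Sd = worked_example.Sd
        cg = circ_gip_similarity(Sd)
        dg = disease_gip_similarity(Sd)
        assert cg.ids == Sd.row_ids
        assert dg.ids == Sd.col_ids
        # delta for circRNAs: mean squared row norm = 8/5
        assert cg.values[0, 1] == pytest.approx(np.exp(-1.6))


def random_dag(rng, n_nodes):
    """Random DAG via a random topological order with random forward edges."""
    order = rng.permutation(n_nodes)
    g = nx.DiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.3:
                g.add_edge(f"n{order[i]}", f"n{order[j]}")
    return DiseaseDAG(g)


class TestSemanticContribution:
    def test_self_contribution_is_one(self):
        dag = DiseaseDAG.from_edges([("r", "a"), ("a", "d")])
        assert semantic_contribution(dag, "d")["d"] == 1.0

    def test_chain_decay(self):
        dag = DiseaseDAG.from_edges([("r", "a"), ("a", "d")])
        g = semantic_contribution(dag, "d")
        assert g == {"d": 1.0, "a": 0.5, "r": 0.25}

    def test_diamond_takes_max_over_paths(self):
        dag = DiseaseDAG.from_edges([("r", "a"), ("r", "b"), ("a", "d"), ("b", "d")])
        g = semantic_contribution(dag, "d")
        assert g["r"] == pytest.approx(0.25)

    def test_uncovered_disease_rejected(self):
        dag = DiseaseDAG.from_edges([("r", "a")])
        with pytest.raises(CoverageError):
            semantic_contribution(dag, "zzz")

    def test_equals_mu_power_shortest_path_on_random_dags(self, rng):
        mu = 0.5
        for _ in range(60):
            dag = random_dag(rng, int(rng.integers(2, 12)))
            d = f"n{rng.integers(len(dag.nodes))}"
            contrib = semantic_contribution(dag, d, SemanticParams(mu=mu))
            for k, g in contrib.items():
                # oracle: exhaustive shortest directed path length k -> d
                sp = nx.shortest_path_length(dag.graph, k, d)
                assert g == pytest.approx(mu**sp)
            assert set(contrib) == dag.ancestor_set(d)


class TestSemanticSimilarity:
    def chains(self):
        return DiseaseDAG.from_edges([("r", "a"), ("a", "d1"), ("r", "b"), ("b", "d2")])

    def test_ds1_unit_diagonal_and_known_value(self):
        dag = self.chains()
        m = semantic_similarity_1(dag, ["d1", "d2"])
        assert m.values[0, 0] == pytest.approx(1.0)
        # shared set {r}: (0.25+0.25)/(1.75+1.75) = 1/7
        assert m.values[0, 1] == pytest.approx(1 / 7)

    def test_ds1_disjoint_dags_score_zero(self):
        dag = DiseaseDAG.from_edges([("r1", "d1"), ("r2", "d2")])
        m = semantic_similarity_1(dag, ["d1", "d2"])
        assert m.values[0, 1] == 0.0

    def test_ds1_uncovered_disease_zero_row(self):
        dag = self.chains()
        m = semantic_similarity_1(dag, ["d1", "dx"])
        assert m.values[1, :].sum() == 0.0

    def test_ds1_bounds_and_symmetry(self, rng):
        for _ in range(20):
            dag = random_dag(rng, 8)
            ids = [f"n{i}" for i in range(8)]
            m = semantic_similarity_1(dag, ids)
            assert (m.values >= 0).all() and (m.values <= 1 + 1e-12).all()
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 1.0)

    def test_ds2_two_disease_universe(self):
        # G'(r)=log(1)=0 since r is in both DAGs; shared set {r} contributes 0
        dag = self.chains()
        m = semantic_similarity_2(dag, ["d1", "d2"])
        assert m.values[0, 1] == pytest.approx(0.0)
        assert m.values[0, 0] == pytest.approx(1.0)  # primed denominator default

    def test_ds2_as_printed_denominator(self):
        dag = DiseaseDAG.from_edges([("r", "d1"), ("r", "d2"), ("d2", "d3")])
        ids = ["d1", "d2", "d3"]
        primed = semantic_similarity_2(dag, ids)
        printed = semantic_similarity_2(
            dag, ids, SemanticParams(ds2_denominator="as_printed")
        )
        # shared set of (d2, d3) is {d2, r} with G'(d2) = log(3/2), G'(r) = 0
        num = 2 * np.log(1.5)
        assert primed.values[1, 2] == pytest.approx(num / (2 * np.log(1.5) + np.log(3)))
        # printed form normalises by the level-decay totals 1.5 + 1.75 instead
        assert printed.values[1, 2] == pytest.approx(num / 3.25)

    def test_ds2_log_base_rescales_scores(self):
        dag = DiseaseDAG.from_edges([("r", "d1"), ("r", "d2"), ("d2", "d3")])
        nat = semantic_similarity_2(dag, ["d1", "d2", "d3"])
        b2 = semantic_similarity_2(dag, ["d1", "d2", "d3"], SemanticParams(log_base=2.0))
        # ratios of G' are base-independent, so DS2 is too
        assert np.allclose(nat.values, b2.values)
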