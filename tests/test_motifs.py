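"""Motif census, feedback-loop enumeration, and the positive-feedback predicate."""

import itertools

import numpy as np
import pytest

from wormcircuit import (
    CircuitModel,
    Connectome,
    InvalidInputError,
    check_sufficiency,
    enumerate_feedback_loops,
    scan_bistability_motifs,
)
from .conftest import mutual_pair, one_neuron


def connectome_from_matrices(neurons, chem, gap, signs=None):
    chem = np.asarray(chem)
    gap = np.asarray(gap)
    edges = {}
    for i, post in enumerate(neurons):
        for j, pre in enumerate(neurons):
            if chem[i, j]:
                edges[(pre, post)] = {
                    "count": int(chem[i, j]),
                    "sign": signs.get((pre, post)) if signs else None,
                }
    gaps = {}
    for i in range(len(neurons)):
        for j in range(i, len(neurons)):  # keep self gaps for the census
            if gap[i, j]:
                gaps[tuple(sorted((neurons[i], neurons[j])))] = int(gap[i, j])
    return Connectome(neurons=tuple(neurons), chem=edges, gap=gaps)


class TestMotifCensus:
    def test_reciprocal_chemical_pair_only(self):
        c = connectome_from_matrices(
            ("A", "B"), [[0, 1], [1, 0]], np.zeros((2, 2), dtype=int)
        )
        assert scan_bistability_motifs(c).counts == {
            "self_chem": 0, "self_chem_gap": 0, "pair_chem": 1, "pair_chem_gap": 0,
        }

    def test_reciprocal_pair_with_gap(self):
        """AVAL-AVAR-style motif: chemical synapses both ways plus a gap junction."""
        c = connectome_from_matrices(
            ("AVAL", "AVAR"), [[0, 7], [9, 0]], [[0, 8], [8, 0]]
        )
        census = scan_bistability_motifs(c)
        assert census.counts["pair_chem"] == 1
        assert census.counts["pair_chem_gap"] == 1
        assert census.pair_chem_gap == [("AVAL", "AVAR")]

    def test_empty_connectome(self):
        c = Connectome(neurons=("A",), chem={}, gap={})
        assert all(v == 0 for v in scan_bistability_motifs(c).counts.values())

    def test_classes_are_nested(self):
        c = connectome_from_matrices(
            ("A", "B", "C"),
            [[1, 1, 0], [1, 0, 0], [0, 0, 1]],
            [[1, 1, 0], [1, 0, 0], [0, 0, 0]],
        )
        census = scan_bistability_motifs(c)
        assert set(census.self_chem_gap) <= set(census.self_chem)
        assert set(census.pair_chem_gap) <= set(census.pair_chem)

    def test_census_matches_brute_force_on_random_connectomes(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 6
            neurons = tuple(f"n{i}" for i in range(n))
            chem = rng.integers(0, 2, (n, n))
            gu = np.triu(rng.integers(0, 2, (n, n)))
            gap = gu + np.triu(gu, 1).T  # symmetric, may include diagonal
            c = connectome_from_matrices(neurons, chem, gap)
            census = scan_bistability_motifs(c).counts
            # brute-force double loop over the adjacency matrices
            self_chem = sum(1 for i in range(n) if chem[i, i])
            self_gap = sum(1 for i in range(n) if chem[i, i] and gap[i, i])
            pair = sum(
                1 for i in range(n) for j in range(i + 1, n)
                if chem[i, j] and chem[j, i]
            )
            pair_gap = sum(
                1 for i in range(n) for j in range(i + 1, n)
                if chem[i, j] and chem[j, i] and gap[i, j]
            )
            assert census == {
                "self_chem": self_chem, "self_chem_gap": self_gap,
                "pair_chem": pair, "pair_chem_gap": pair_gap,
            }


class TestFeedbackLoops:
    def test_excitatory_self_loop(self):
        loops = enumerate_feedback_loops(one_neuron(2.0), max_len=1)
        assert len(loops) == 1
        (loop,) = loops
        assert len(loop) == 1 and loop.sign_product == 1 and loop.excitatory_only

    def test_mutual_inhibition_has_positive_sign_product(self):
        m = CircuitModel(names=("A", "B"), W=[[0, -2], [-2, 0]], G=np.zeros((2, 2)))
        loops = enumerate_feedback_loops(m, max_len=2)
        assert len(loops) == 1
        assert loops[0].sign_product == 1  # (-1)(-1) = +1
        assert not loops[0].excitatory_only

    def test_feedforward_chain_has_no_loops(self):
        W = np.zeros((3, 3))
        W[1, 0] = W[2, 1] = 1.0  # A -> B -> C
        m = CircuitModel(names=("A", "B", "C"), W=W, G=np.zeros((3, 3)))
        assert enumerate_feedback_loops(m, max_len=3) == []

    def test_unsigned_chemical_edge_rejected(self):
        c = Connectome(
            neurons=("A", "B"),
            chem={("A", "B"): {"count": 1, "sign": None}, ("B", "A"): {"count": 1, "sign": 1}},
            gap={},
        )
        with pytest.raises(InvalidInputError, match="sign"):
            enumerate_feedback_loops(c, max_len=2)

    def test_complete_signed_digraph_matches_permutation_oracle(self):
        """Node-cycle enumeration on K5 agrees with exhaustive permutation counting."""
        n = 5
        rng = np.random.default_rng(5)
        W = rng.choice([-1.0, 1.0], size=(n, n))
        np.fill_diagonal(W, 0.0)
        m = CircuitModel(names=tuple("ABCDE"), W=W, G=np.zeros((n, n)))
        loops = enumerate_feedback_loops(m, max_len=n)
        # oracle: distinct rotations of node sequences of length 2..n
        expected = set()
        for k in range(2, n + 1):
            for perm in itertools.permutations(range(n), k):
                if perm[0] != min(perm):
                    continue  # canonical rotation
                expected.add(perm)
        names = m.names
        got = set()
        for loop in loops:
            idx = tuple(names.index(x) for x in loop.nodes)
            rot = idx.index(min(idx))
            got.add(idx[rot:] + idx[:rot])
        assert got == expected
        # spot-check sign products against direct multiplication
        for loop in loops[:20]:
            prod = 1
            for e in loop.edges:
                prod *= int(np.sign(W[names.index(e["post"]), names.index(e["pre"])]))
            assert prod == loop.sign_product


class TestSufficiency:
    def test_self_loop_satisfies_with_unit_witness(self):
        res = check_sufficiency(one_neuron(2.0))
        assert res["satisfied"] and len(res["witness"]) == 1

    def test_feedforward_dag_not_satisfied(self):
        W = np.zeros((3, 3))
        W[1, 0] = W[2, 1] = 1.0
        m = CircuitModel(names=("A", "B", "C"), W=W, G=np.zeros((3, 3)))
        assert not check_sufficiency(m)["satisfied"]

    def test_mutual_inhibition_strict_vs_lenient(self):
        m = CircuitModel(names=("A", "B"), W=[[0, -2], [-2, 0]], G=np.zeros((2, 2)))
        assert not check_sufficiency(m, strict=True)["satisfied"]
        assert check_sufficiency(m, strict=False)["satisfied"]

    def test_every_multistable_fixture_satisfies_predicate(self, command_model):
        """Consistency of the structural predicate with the solver: every circuit in
        the fixture library with >= 2 fixed points has an excitatory positive loop."""
        from wormcircuit import find_fixed_points

        fixtures = [one_neuron(2.0), mutual_pair(2.0), mutual_pair(2.5, g=0.5), command_model]
        for m in fixtures:
            fps = find_fixed_points(m, box=(-3.0, 3.0), n_starts=100, seed=0)
            if len(fps) >= 2:
                assert check_sufficiency(m)["satisfied"]
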