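"""Adjacency IO, rule-based weight assignment, fixture integrity, deductions."""

import numpy as np
import pytest

from wormcircuit import (
    AdjustmentRules,
    CircuitModel,
    GroupAssignment,
    InvalidStructureError,
    build_circuit,
    command_circuit_fixture,
    constraint_holds,
    deduce_structure_constraints,
    find_fixed_points,
    read_adjacency_csv,
)
from wormcircuit.connectome import _build_command_circuit, command_circuit_groups


def write_matrices(tmp_path, neurons, chem, gap):
    def fmt(mat):
        lines = ["," + ",".join(neurons)]
        for name, row in zip(neurons, mat):
            lines.append(name + "," + ",".join(str(v) for v in row))
        return "\n".join(lines) + "\n"

    cp = tmp_path / "chem.csv"
    gp = tmp_path / "gap.csv"
    cp.write_text(fmt(chem))
    gp.write_text(fmt(gap))
    return cp, gp


class TestReadAdjacencyCsv:
    def test_orientation_entry_ij_means_j_onto_i(self, tmp_path):
        cp, gp = write_matrices(tmp_path, ["A", "B"], [[0, 3], [1, 0]], [[0, 0], [0, 0]])
        c = read_adjacency_csv(cp, gp)
        assert c.chem[("B", "A")]["count"] == 3
        assert c.chem[("A", "B")]["count"] == 1

    def test_gap_edge_stored_once_per_pair(self, tmp_path):
        cp, gp = write_matrices(tmp_path, ["A", "B"], [[0, 0], [0, 0]], [[0, 8], [8, 0]])
        c = read_adjacency_csv(cp, gp)
        assert c.gap == {("A", "B"): 8}

    def test_asymmetric_gap_matrix_names_offending_pair(self, tmp_path):
        cp, gp = write_matrices(tmp_path, ["A", "B"], [[0, 0], [0, 0]], [[0, 2], [1, 0]])
        with pytest.raises(InvalidStructureError, match="A.*B"):
            read_adjacency_csv(cp, gp)

    def test_nonsquare_rejected(self, tmp_path):
        cp = tmp_path / "chem.csv"
        cp.write_text(",A,B\nA,0,1\n")
        gp = tmp_path / "gap.csv"
        gp.write_text(",A,B\nA,0,0\nB,0,0\n")
        with pytest.raises(InvalidStructureError):
            read_adjacency_csv(cp, gp)

    def test_header_mismatch_between_files_rejected(self, tmp_path):
        cp, _ = write_matrices(tmp_path, ["A", "B"], [[0, 1], [1, 0]], [[0, 0], [0, 0]])
        _, gp = write_matrices(tmp_path / "..", ["A", "C"], [[0, 0], [0, 0]], [[0, 0], [0, 0]])
        with pytest.raises(InvalidStructureError):
            read_adjacency_csv(cp, gp)


class TestBuildCircuit:
    @pytest.fixture()
    def toy(self, tmp_path):
        neurons = ["AVAL", "AVAR", "AVBL"]
        chem = [[0, 7, 1], [9, 0, 0], [0, 3, 0]]  # entry (i,j) = j -> i
        gap = [[0, 8, 0], [8, 0, 0], [0, 0, 0]]
        cp, gp = write_matrices(tmp_path, neurons, chem, gap)
        conn = read_adjacency_csv(cp, gp)
        groups = GroupAssignment(
            sections={"AVAL": "backward", "AVAR": "backward", "AVBL": "forward"},
            pairs={"AVAL": "AVAR"},
        )
        return conn, groups

    def test_same_section_high_count_saturates_positive(self, toy):
        conn, groups = toy
        m = build_circuit(conn, groups)
        # AVAL -> AVAR carries 9 synapses within one section: capped at +1
        assert m.W[m.index("AVAR"), m.index("AVAL")] == 1.0
        assert m.W[m.index("AVAL"), m.index("AVAR")] == 1.0  # 7 synapses also at cap

    def test_cross_section_edge_is_negative(self, toy):
        conn, groups = toy
        m = build_circuit(conn, groups)
        assert m.W[m.index("AVBL"), m.index("AVAR")] < 0  # 3 synapses across sections

    def test_sparse_edge_gets_weak_weight(self, toy):
        conn, groups = toy
        m = build_circuit(conn, groups)
        # 1 synapse AVBL -> AVAL, across sections: weak magnitude ~ 0.1
        assert m.W[m.index("AVAL"), m.index("AVBL")] == pytest.approx(-0.1)

    def test_intra_pair_gap_in_stated_range(self, toy):
        conn, groups = toy
        m = build_circuit(conn, groups)
        g = m.G[m.index("AVAL"), m.index("AVAR")]
        assert 1.0 <= g <= 2.0

    def test_magnitude_map_is_monotone(self):
        rules = AdjustmentRules()
        mags = [rules.chem_magnitude(c) for c in range(0, 12)]
        assert all(a <= b for a, b in zip(mags, mags[1:]))
        assert rules.chem_magnitude(1) == rules.chem_magnitude(2) == 0.1
        assert rules.chem_magnitude(7) == 1.0 == rules.chem_magnitude(11)

    def test_ungrouped_neuron_rejected(self, toy):
        conn, _ = toy
        bad = GroupAssignment(sections={"AVAL": "backward"})
        with pytest.raises(Exception):
            build_circuit(conn, bad)

    def test_sign_safety_never_flips_class(self, toy):
        """Magnitude adjustment never converts excitatory <-> inhibitory."""
        conn, groups = toy
        for sat in (3, 5, 9):
            m = build_circuit(conn, groups, AdjustmentRules(saturation_count=sat))
            for (pre, post) in conn.chem:
                w = m.W[m.index(post), m.index(pre)]
                assert (w > 0) == groups.same_section(pre, post)


class TestCommandFixture:
    def test_packaged_json_matches_builder(self, command_model):
        built = _build_command_circuit()
        assert built.names == command_model.names
        assert np.array_equal(built.W, command_model.W)
        assert np.array_equal(built.G, command_model.G)

    def test_parameters(self, command_model):
        assert (command_model.tau, command_model.theta, command_model.k) == (1.0, 0.5, 20.0)
        assert command_model.names[0] == "AVBL" and command_model.n == 10

    def test_three_attractors_with_reported_activation_patterns(self, command_fps, command_model):
        stable = command_fps.stable_points
        assert len(stable) == 3
        from wormcircuit import activation_pattern

        pats = {frozenset(activation_pattern(p.x, command_model)) for p in stable}
        assert pats == {
            frozenset({"AVBL", "AVBR"}),
            frozenset({"AVAL", "AVAR", "AVEL", "AVER"}),
            frozenset(),
        }

    def test_forward_point_signs(self, command_fps, command_model):
        fwd = next(
            p for p in command_fps.stable_points
            if p.x[command_model.index("AVBL")] > command_model.theta
        )
        names = command_model.names
        for nm in names:
            v = fwd.x[command_model.index(nm)]
            if nm.startswith("AVB"):
                assert v > command_model.theta
            else:
                assert v <= 0.0, nm

    def test_quiescent_point_rounds_to_zero(self, command_fps):
        q = min(command_fps.stable_points, key=lambda p: np.max(np.abs(p.x)))
        assert np.all(q.rounded == 0.0)

    def test_weight_rules_respected(self, command_model):
        groups = command_circuit_groups()
        m = command_model
        assert np.abs(m.W).max() <= 1.0
        for i, post in enumerate(m.names):
            for j, pre in enumerate(m.names):
                if m.W[i, j] != 0.0:
                    assert (m.W[i, j] > 0) == groups.same_section(pre, post)
        for a, b in [("AVBL", "AVBR"), ("PVCL", "PVCR"), ("AVAL", "AVAR"),
                     ("AVDL", "AVDR"), ("AVEL", "AVER")]:
            assert 1.0 <= m.G[m.index(a), m.index(b)] <= 2.0
        # cross-section gaps weaker than intra-pair gaps
        assert m.G[m.index("AVAL"), m.index("PVCL")] < 1.0

    def test_fixture_round_trips_through_json(self, command_model, tmp_path):
        p = tmp_path / "fixture.json"
        command_model.to_json(p)
        back = CircuitModel.from_json(p)
        assert np.array_equal(back.W, command_model.W)
        assert np.array_equal(back.G, command_model.G)


class TestStructureDeduction:
    ROLES = dict(
        state_formers={
            "forward": ("AVBL", "AVBR"),
            "backward": ("AVAL", "AVAR", "AVEL", "AVER"),
        },
        basin_formers={"forward": ("PVCL", "PVCR"), "backward": ("AVDL", "AVDR")},
        pairs={"AVBL": "AVBR", "AVAL": "AVAR", "AVEL": "AVER",
               "PVCL": "PVCR", "AVDL": "AVDR"},
    )

    def test_command_roles_emit_expected_rule_instances(self):
        cons = deduce_structure_constraints(**self.ROLES)
        kinds = [c.kind for c in cons]
        assert kinds.count("strong-reciprocal") == 3  # AVB, AVA, AVE pairs
        assert kinds.count("weak-or-gap-only") == 2  # PVC, AVD pairs
        assert kinds.count("mutual-inhibition") == 1
        strong = {c.subjects for c in cons if c.kind == "strong-reciprocal"}
        assert ("AVBL", "AVBR") in strong

    def test_deterministic_ordering(self):
        a = deduce_structure_constraints(**self.ROLES)
        b = deduce_structure_constraints(**self.ROLES)
        assert a == b

    def test_amphid_roles_include_state_former_inhibition(self):
        cons = deduce_structure_constraints(
            state_formers={"odor-on": ("AIBL", "AIBR"), "odor-off": ("AIYL", "AIYR")},
            basin_formers={"odor-on": ("AIZL", "AIZR"), "odor-off": ("AIAL", "AIAR")},
            pairs={"AIBL": "AIBR", "AIYL": "AIYR", "AIZL": "AIZR", "AIAL": "AIAR"},
        )
        mut = [c for c in cons if c.kind == "mutual-inhibition"]
        assert len(mut) == 1
        assert set(mut[0].subjects) | set(mut[0].objects) == {
            "AIBL", "AIBR", "AIYL", "AIYR"
        }

    def test_no_basin_formers_emits_state_rules_only(self):
        cons = deduce_structure_constraints(
            state_formers={"up": ("A", "B")}, pairs={"A": "B"}
        )
        assert {c.kind for c in cons} == {"strong-reciprocal"}

    def test_all_constraints_hold_in_the_fixture(self, command_model):
        """Every deduced command-circuit constraint is realized by the fixture weights."""
        cons = deduce_structure_constraints(**self.ROLES)
        for c in cons:
            assert constraint_holds(c, command_model), c
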