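"""Contact computation, Table-style classification, and graph assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plimotif.atom_typing import PHYSCHEM_TYPES, TypedAtom
from plimotif.interaction_graph import (
    DEFAULT_CRITERIA,
    DistanceCriteria,
    build_pli_graph,
    classify_interactions,
    compute_contacts,
    graph_from_json,
    graph_to_json,
)
from plimotif.structure_io import AtomRecord, extract_ligands, parse_pdb, strip_hydrogens
from plimotif.fixtures import InterfaceContact, make_profile_complex


def _typed(role, types, xyz, serial=1):
    a = AtomRecord(serial=serial, atom_name="X", element="C", alt_loc="",
                   residue_name="GLY" if role == "protein" else "LIG",
                   residue_number=serial, insertion_code="", chain_id="A",
                   x=xyz[0], y=xyz[1], z=xyz[2],
                   record_kind="polymer" if role == "protein" else "hetero")
    return TypedAtom(atom=a, molecule_role=role, types=frozenset(types))


class TestCriteria:
    def test_default_windows(self):
        assert DEFAULT_CRITERIA.window("aromatic_stacking") == (1.5, 3.5)
        assert DEFAULT_CRITERIA.window("hydrogen_bond") == (2.0, 3.0)
        assert DEFAULT_CRITERIA.window("hydrophobic") == (2.0, 3.8)
        assert DEFAULT_CRITERIA.window("repulsive") == (2.0, 6.0)
        assert DEFAULT_CRITERIA.window("salt_bridge") == (2.0, 6.0)
        assert DEFAULT_CRITERIA.global_cutoff == 6.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            DistanceCriteria(windows=(("aromatic_stacking", 3.5, 1.5),
                                      ("hydrogen_bond", 2.0, 3.0),
                                      ("hydrophobic", 2.0, 3.8),
                                      ("repulsive", 2.0, 6.0),
                                      ("salt_bridge", 2.0, 6.0)))

    def test_replace_and_round_trip(self):
        c = DEFAULT_CRITERIA.replace(hydrophobic=(2.5, 4.0))
        assert c.window("hydrophobic") == (2.5, 4.0)
        assert DistanceCriteria.from_dict(c.to_dict()) == c


class TestComputeContacts:
    def test_boundary_distance_included(self):
        p = [_typed("protein", {"hydrophobic"}, (0, 0, 0))]
        l = [_typed("ligand", {"hydrophobic"}, (0, 0, 6.0), serial=2)]
        contacts = compute_contacts(p, l, 6.0)
        assert len(contacts) == 1
        assert contacts[0][2] == pytest.approx(6.0)

    def test_beyond_cutoff_excluded(self):
        p = [_typed("protein", {"hydrophobic"}, (0, 0, 0))]
        l = [_typed("ligand", {"hydrophobic"}, (0, 0, 6.01), serial=2)]
        assert compute_contacts(p, l, 6.0) == []

    def test_cross_product_count(self):
        p = [_typed("protein", {"hydrophobic"}, (i, 0, 0), serial=i + 1) for i in range(3)]
        l = [_typed("ligand", {"hydrophobic"}, (i, 1, 0), serial=10 + i) for i in range(2)]
        assert len(compute_contacts(p, l, 6.0)) == 6

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        p = [_typed("protein", {"hydrophobic"}, tuple(rng.uniform(0, 10, 3)), serial=i)
             for i in range(1, 15)]
        l = [_typed("ligand", {"hydrophobic"}, tuple(rng.uniform(0, 10, 3)), serial=100 + i)
             for i in range(12)]
        got = {(i, j, round(d, 9)) for i, j, d in compute_contacts(p, l, 6.0)}
        expected = set()
        for i, tp in enumerate(p):
            for j, tl in enumerate(l):
                d = float(np.linalg.norm(np.array(tp.atom.coord) - np.array(tl.atom.coord)))
                if d <= 6.0:
                    expected.add((i, j, round(d, 9)))
        assert got == expected


class TestClassifyInteractions:
    @pytest.mark.parametrize("ti,tj,d,expected", [
        ({"hydrophobic"}, {"hydrophobic"}, 3.0, {"hydrophobic"}),
        ({"hydrophobic"}, {"hydrophobic"}, 3.9, set()),
        ({"acceptor", "negative"}, {"acceptor", "negative"}, 5.0, {"repulsive"}),
        ({"donor", "positive"}, {"acceptor", "negative"}, 2.5,
         {"hydrogen_bond", "salt_bridge"}),
        ({"aromatic", "hydrophobic"}, {"aromatic", "hydrophobic"}, 3.4,
         {"aromatic_stacking", "hydrophobic"}),
        ({"aromatic"}, {"aromatic"}, 1.5, {"aromatic_stacking"}),  # lower bound inclusive
        ({"aromatic"}, {"aromatic"}, 1.4, set()),
        ({"donor"}, {"acceptor"}, 3.0, {"hydrogen_bond"}),  # upper bound inclusive
        ({"donor"}, {"acceptor"}, 3.01, set()),
        ({"positive"}, {"positive"}, 6.0, {"repulsive"}),
        ({"negative"}, {"positive"}, 6.0, {"salt_bridge"}),
        ({"donor"}, {"donor"}, 2.5, set()),  # donor-donor is nothing
        (set(), {"hydrophobic"}, 3.0, set()),
    ])
    def test_rule_table(self, ti, tj, d, expected):
        assert classify_interactions(ti, tj, d) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        ti=st.sets(st.sampled_from(PHYSCHEM_TYPES), max_size=3),
        tj=st.sets(st.sampled_from(PHYSCHEM_TYPES), max_size=3),
        d=st.floats(min_value=0.1, max_value=8.0, allow_nan=False),
    )
    def test_symmetry(self, ti, tj, d):
        assert classify_interactions(ti, tj, d) == classify_interactions(tj, ti, d)

    @settings(max_examples=100, deadline=None)
    @given(
        ti=st.sets(st.sampled_from(PHYSCHEM_TYPES), max_size=3),
        tj=st.sets(st.sampled_from(PHYSCHEM_TYPES), max_size=3),
        d=st.floats(min_value=0.1, max_value=8.0, allow_nan=False),
    )
    def test_every_result_obeys_its_window(self, ti, tj, d):
        for interaction in classify_interactions(ti, tj, d):
            lo, hi = DEFAULT_CRITERIA.window(interaction)
            assert lo <= d <= hi


def _build_fixture_graph(contacts, criteria=DEFAULT_CRITERIA):
    from plimotif.atom_typing import default_typing_table
    text, overrides = make_profile_complex("fix", contacts)
    model = strip_hydrogens(parse_pdb(text, "fix"))
    ligand = extract_ligands(model, "A")[0]
    return build_pli_graph(model, "A", ligand, default_typing_table(),
                           criteria, overrides)


class TestBuildPliGraph:
    CONTACTS = [
        InterfaceContact("SER", "OG", ("acceptor",), 2.5),        # 1 H-bond
        InterfaceContact("LEU", "CD1", ("hydrophobic",), 3.5),    # hydrophobic
        InterfaceContact("VAL", "CG1", ("hydrophobic",), 3.6),    # hydrophobic
    ]

    def test_engineered_edge_multiset(self):
        g = _build_fixture_graph(self.CONTACTS)
        labels = sorted(d["interaction"] for _, _, d in g.graph.edges(data=True))
        assert labels == ["hydrogen_bond", "hydrophobic", "hydrophobic"]

    def test_bipartite(self):
        g = _build_fixture_graph(self.CONTACTS)
        assert g.is_bipartite()

    def test_far_ligand_yields_no_graph(self):
        g = _build_fixture_graph([InterfaceContact("LEU", "CD1", ("hydrophobic",), 10.0)])
        assert g is None

    def test_no_isolated_nodes(self):
        g = _build_fixture_graph(self.CONTACTS)
        assert all(deg > 0 for _, deg in g.graph.degree())

    def test_window_soundness_perturbing_criteria_removes_edge(self):
        shrunk = DEFAULT_CRITERIA.replace(hydrophobic=(2.0, 3.4))
        g = _build_fixture_graph(self.CONTACTS, shrunk)
        labels = sorted(d["interaction"] for _, _, d in g.graph.edges(data=True))
        assert labels == ["hydrogen_bond"]

    def test_monotonicity_enlarging_windows_never_loses_edges(self):
        base = _build_fixture_graph(self.CONTACTS)
        widened = DistanceCriteria(windows=tuple(
            (name, lo, hi + 1.0) for name, lo, hi in DEFAULT_CRITERIA.windows))
        bigger = _build_fixture_graph(self.CONTACTS, widened)
        assert bigger.n_edges >= base.n_edges

    def test_parallel_edges_for_multi_type_pairs(self):
        g = _build_fixture_graph(
            [InterfaceContact("PHE", "CZ", ("aromatic", "hydrophobic"), 3.4)])
        labels = sorted(d["interaction"] for _, _, d in g.graph.edges(data=True))
        assert labels == ["aromatic_stacking", "hydrophobic"]
        assert g.graph.number_of_nodes() == 2  # parallel, same atom pair

    def test_edges_match_brute_force_rule_evaluation(self):
        g = _build_fixture_graph(self.CONTACTS)
        # Independent O(|P|*|L|) loop over typed atoms with direct rules.
        from plimotif.atom_typing import default_typing_table, type_protein_atoms, type_ligand_atoms
        from plimotif.structure_io import protein_atoms
        text, overrides = make_profile_complex("fix", self.CONTACTS)
        model = strip_hydrogens(parse_pdb(text, "fix"))
        ligand = extract_ligands(model, "A")[0]
        prot = type_protein_atoms(protein_atoms(model, "A"), default_typing_table())
        lig = type_ligand_atoms(ligand, overrides)
        expected = []
        for p in prot:
            for l in lig:
                d = float(np.linalg.norm(np.array(p.atom.coord) - np.array(l.atom.coord)))
                for it in classify_interactions(p.types, l.types, d):
                    expected.append((p.atom.serial, l.atom.serial, it))
        got = [(g.graph.nodes[u]["serial"], g.graph.nodes[v]["serial"], d["interaction"])
               if g.graph.nodes[u]["role"] == "protein"
               else (g.graph.nodes[v]["serial"], g.graph.nodes[u]["serial"], d["interaction"])
               for u, v, d in g.graph.edges(data=True)]
        assert sorted(got) == sorted(expected)

    def test_json_round_trip(self):
        g = _build_fixture_graph(self.CONTACTS)
        again = graph_from_json(graph_to_json(g))
        assert graph_to_json(again) == graph_to_json(g)

    def test_graphml_written(self, tmp_path):
        g = _build_fixture_graph(self.CONTACTS)
        path = tmp_path / "g.graphml"
        from plimotif.interaction_graph import write_graphml
        write_graphml(g, path)
        import networkx as nx
        loaded = nx.read_graphml(path)
        assert loaded.number_of_edges() == g.n_edges
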