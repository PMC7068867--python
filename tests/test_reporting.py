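"""Pipeline orchestration, analytic tables, persistence, and the CLI."""

import hashlib
import json
from pathlib import Path

import pytest

from plimotif.motif_mining import MotifGraph, motif_contained_in
from plimotif.reporting import (
    RunConfig,
    histograms,
    load_bundle,
    patterns_table,
    run_project,
    search_residue,
)


@pytest.fixture(scope="module")
def family_bundle(family_dataset, tmp_path_factory):
    structures, overrides, _ = family_dataset
    out = tmp_path_factory.mktemp("family_run")
    config = RunConfig(structures=structures, k_range=[2, 3, 4], seed=1,
                       support_fractions=(0.6, 1.0), output_dir=str(out))
    return run_project(config, overrides=overrides), out


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestRunProject:
    def test_two_families_give_two_clusters(self, family_bundle):
        bundle, _ = family_bundle
        model = bundle.cluster_model
        assert model.k == 2
        groups = {}
        for gid, lab in model.labels.items():
            groups.setdefault(gid.split(".")[0][:4], set()).add(lab)
        assert groups["famA"] != groups["famB"]
        assert all(len(v) == 1 for v in groups.values())

    def test_engineered_shared_motif_maximal_in_each_family(self, family_bundle):
        bundle, _ = family_bundle
        # Family B's shared profile includes the connected 3-node
        # double-repulsive subgraph around the shared O1G-type atom.
        import networkx as nx
        expect = nx.MultiGraph()
        for n, lab in {0: "P:acceptor,negative", 1: "L:acceptor,negative",
                       2: "P:acceptor,negative"}.items():
            expect.add_node(n, label=lab)
        expect.add_edge(0, 1, label="repulsive")
        expect.add_edge(1, 2, label="repulsive")
        target = MotifGraph(graph=expect, support_count=0, support_fraction=1.0,
                            graph_ids=[])
        groups_b = {lab for gid, lab in bundle.cluster_model.labels.items()
                    if gid.startswith("famB")}
        (group_b,) = groups_b
        maximal = bundle.motifs[(group_b, 1.0)]
        assert any(motif_contained_in(target, m) for m in maximal)

    def test_rerun_same_config_and_seed_byte_identical(self, family_dataset,
                                                       tmp_path):
        structures, overrides, _ = family_dataset
        digests = []
        for name in ("r1", "r2"):
            out = tmp_path / name
            config = RunConfig(structures=structures, k_range=[2, 3], seed=7,
                               support_fractions=(0.6,), output_dir=str(out))
            run_project(config, overrides=overrides)
            digests.append(_tree_digest(out))
        assert digests[0] == digests[1]

    def test_single_support_fraction_one_sweep_point_per_cluster(self, family_dataset,
                                                                 tmp_path):
        structures, overrides, _ = family_dataset
        config = RunConfig(structures=structures, k_range=[2], seed=0,
                           support_fractions=(0.6,))
        bundle = run_project(config, overrides=overrides)
        fractions = {f for (_g, f) in bundle.motifs}
        assert fractions == {0.6}
        groups = {g for (g, _f) in bundle.motifs}
        assert groups == set(bundle.cluster_model.groups())

    def test_unparseable_structure_skipped_not_fatal(self, family_dataset, tmp_path):
        structures, overrides, _ = family_dataset
        bad = tmp_path / "broken.pdb"
        bad.write_text("HEADER    NOTHING HERE\nEND\n")
        config = RunConfig(structures=[(str(bad), "A")] + structures,
                           k_range=[2], seed=0, support_fractions=(0.6,))
        bundle = run_project(config, overrides=overrides)
        assert len(bundle.graphs) == 6
        assert any(d["structure"] == "broken" for d in bundle.dropped)


class TestTables:
    def test_patterns_table_counts_conserve(self, family_bundle):
        bundle, _ = family_bundle
        table = patterns_table(bundle)
        for (group, fraction), motifs in bundle.motifs.items():
            sub = table[(table.group == group) & (table.support_fraction == fraction)]
            assert sub.occurrences.sum() == len(motifs)

    def test_histogram_interaction_counts_conserve(self, family_bundle):
        bundle, _ = family_bundle
        hist = histograms(bundle, "interaction_type", "group")
        total_edges = sum(m.n_edges for motifs in bundle.motifs.values() for m in motifs)
        assert hist["count"].sum() == total_edges

    def test_histogram_atom_type_counts_conserve(self, family_bundle):
        bundle, _ = family_bundle
        hist = histograms(bundle, "atom_type", "group")
        total = sum(len(d["label"].split(":", 1)[1].split(","))
                    for motifs in bundle.motifs.values() for m in motifs
                    for _n, d in m.graph.nodes(data=True))
        assert hist["count"].sum() == total

    def test_repulsive_modal_in_charged_family(self, family_bundle):
        bundle, _ = family_bundle
        groups_b = {lab for gid, lab in bundle.cluster_model.labels.items()
                    if gid.startswith("famB")}
        (group_b,) = groups_b
        hist = histograms(bundle, "interaction_type", "group")
        sub = hist[hist.group == group_b].set_index("interaction_type")["count"]
        assert sub.idxmax() == "repulsive"

    def test_empty_mining_result_empty_table(self, family_bundle):
        bundle, _ = family_bundle
        import copy
        empty = copy.copy(bundle)
        empty.motifs = {}
        assert patterns_table(empty).empty

    def test_search_residue_finds_nodes(self, family_bundle):
        bundle, _ = family_bundle
        hits = search_residue(bundle, "SER1")
        assert hits
        g_by_id = bundle.graphs_by_id()
        for gid, node in hits:
            d = g_by_id[gid].graph.nodes[node]
            assert d["residue_name"] == "SER" and d["residue_number"] == 1

    def test_search_no_match_empty(self, family_bundle):
        bundle, _ = family_bundle
        assert search_residue(bundle, "ZZZ999") == []

    def test_search_ligand_atom_name(self, family_bundle):
        bundle, _ = family_bundle
        hits = search_residue(bundle, "O1G")
        assert hits
        g_by_id = bundle.graphs_by_id()
        assert all(g_by_id[g].graph.nodes[n]["atom_name"] == "O1G" for g, n in hits)


class TestPersistence:
    def test_round_trip_reproduces_tables(self, family_bundle):
        bundle, out = family_bundle
        reloaded = load_bundle(out)
        assert patterns_table(reloaded).equals(patterns_table(bundle))
        for facet in ("interaction_type", "atom_type"):
            assert histograms(reloaded, facet, "group").equals(
                histograms(bundle, facet, "group"))
        assert reloaded.matrix.data.equals(bundle.matrix.data)
        assert reloaded.cluster_model.labels == bundle.cluster_model.labels

    def test_expected_artifacts_exist(self, family_bundle):
        _, out = family_bundle
        for name in ("feature_matrix.csv", "clusters.csv", "motifs.json",
                     "embeddings.json", "ligand_atom_stats.csv",
                     "patterns_table.csv", "run_metadata.json"):
            assert (out / name).exists()
        assert list((out / "graphs").glob("*.graphml"))
        assert list((out / "motifs").glob("*.graphml"))


class TestCli:
    def test_criteria_subcommand_prints_defaults(self):
        from click.testing import CliRunner
        from plimotif.cli import main
        result = CliRunner().invoke(main, ["criteria"])
        assert result.exit_code == 0
        crit = json.loads(result.output)
        assert crit["hydrophobic"] == [2.0, 3.8]

    def test_graphs_then_cluster_then_mine(self, family_dataset, tmp_path):
        from click.testing import CliRunner
        from plimotif.cli import main
        structures, _, overrides_path = family_dataset
        listing = tmp_path / "inputs.txt"
        listing.write_text("".join(f"{p} {c}\n" for p, c in structures))
        runner = CliRunner()
        r = runner.invoke(main, ["graphs", str(listing), "-o", str(tmp_path / "g"),
                                 "--overrides", overrides_path])
        assert r.exit_code == 0, r.output
        assert "built 6 graphs" in r.output
        r = runner.invoke(main, ["cluster", str(tmp_path / "g"),
                                 "-o", str(tmp_path / "c"), "--k-max", "3"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["mine", str(tmp_path / "g"),
                                 "-o", str(tmp_path / "m"),
                                 "--clusters", str(tmp_path / "c" / "clusters.csv"),
                                 "--support", "0.6"])
        assert r.exit_code == 0, r.output
        motifs = json.loads((tmp_path / "m" / "motifs.json").read_text())
        assert motifs

    def test_run_subcommand_end_to_end(self, family_dataset, tmp_path):
        from click.testing import CliRunner
        from plimotif.cli import main
        structures, _, overrides_path = family_dataset
        listing = tmp_path / "inputs.txt"
        listing.write_text("".join(f"{p} {c}\n" for p, c in structures))
        out = tmp_path / "run_out"
        r = CliRunner().invoke(main, [
            "run", str(listing), "-o", str(out), "--overrides", overrides_path,
            "--k-max", "3", "--support", "0.6", "--seed", "1"])
        assert r.exit_code == 0, r.output
        assert (out / "run_metadata.json").exists()
        r2 = CliRunner().invoke(main, ["report", str(out)])
        assert r2.exit_code == 0
        assert "group" in r2.output

    def test_inline_criteria_override(self, family_dataset, tmp_path):
        from click.testing import CliRunner
        from plimotif.cli import main
        structures, _, overrides_path = family_dataset
        listing = tmp_path / "inputs.txt"
        listing.write_text(f"{structures[0][0]} {structures[0][1]}\n")
        # Shrinking the hydrophobic window drops that family-A edge.
        r = CliRunner().invoke(main, [
            "graphs", str(listing), "-o", str(tmp_path / "g2"),
            "--overrides", overrides_path, "--criteria", "hydrophobic=2.0:3.2"])
        assert r.exit_code == 0, r.output
        data = json.loads(next((tmp_path / "g2").glob("*.json")).read_text())
        assert all(e["interaction"] != "hydrophobic" for e in data["edges"])
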