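"""End-to-end pipeline orchestration and analytic tables.

``run_project`` drives structures -> typed graphs -> feature matrix ->
clustering -> per-cluster motif mining -> maximal filtering -> embedding
mapping, persisting every artifact (GraphML/JSON/CSV) under the output
directory so a run is reproducible bit-for-bit from its config and seed.
The table builders reproduce the analytic views: the graph-patterns
summary (group x support x motif size occurrence counts), atom-type and
interaction-type histograms over motifs, and residue/atom text search.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from plimotif.structure_io import parse_pdb, strip_hydrogens, extract_ligands, PDBParseError
from plimotif.atom_typing import TypingTable, default_typing_table
from plimotif.interaction_graph import (
    DEFAULT_CRITERIA,
    DistanceCriteria,
    PLIGraph,
    build_pli_graph,
    graph_to_json,
    graph_from_json,
    write_graphml,
)
from plimotif.featurization import DEFAULT_MAX_PATH_LENGTH, FeatureMatrix, assemble_matrix
from plimotif.clustering import ClusterModel, select_model, svd_reduce
from plimotif.motif_mining import (
    DEFAULT_SUPPORT_FRACTIONS,
    LigandAtomStat,
    MotifEmbedding,
    MotifGraph,
    filter_maximal,
    ligand_atom_stats,
    map_embeddings,
    mine_frequent_subgraphs,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    structures: list[tuple[str, str]]  # (path to PDB file, chain id)
    criteria: DistanceCriteria = DEFAULT_CRITERIA
    algorithm: str = "kmedoids"
    metric: str = "asw"
    k_range: Optional[list[int]] = None
    seed: int = 0
    support_fractions: tuple[float, ...] = DEFAULT_SUPPORT_FRACTIONS
    max_path_length: int = DEFAULT_MAX_PATH_LENGTH
    max_motif_edges: Optional[int] = 12
    output_dir: Optional[str] = None
    overrides_path: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "structures": [list(s) for s in self.structures],
            "criteria": self.criteria.to_dict(),
            "algorithm": self.algorithm,
            "metric": self.metric,
            "k_range": list(self.k_range) if self.k_range else None,
            "seed": self.seed,
            "support_fractions": list(self.support_fractions),
            "max_path_length": self.max_path_length,
            "max_motif_edges": self.max_motif_edges,
            "overrides_path": self.overrides_path,
        }


@dataclass
class ResultsBundle:
    config: RunConfig
    graphs: list[PLIGraph]
    matrix: FeatureMatrix
    cluster_model: ClusterModel
    # (cluster id, support fraction) -> maximal motifs
    motifs: dict[tuple[int, float], list[MotifGraph]]
    embeddings: dict[str, list[MotifEmbedding]]  # motif_id -> embeddings
    stats: dict[str, list[LigandAtomStat]]  # motif_id -> per-ligand-atom stats
    dropped: list[dict] = field(default_factory=list)

    def all_motifs(self) -> list[MotifGraph]:
        return [m for motifs in self.motifs.values() for m in motifs]

    def graphs_by_id(self) -> dict[str, PLIGraph]:
        return {g.graph_id: g for g in self.graphs}


def _load_overrides(path: Optional[str]) -> Optional[TypingTable]:
    if path is None:
        return None
    from plimotif.atom_typing import load_typing_table
    return load_typing_table(Path(path).read_text())


def build_graphs_from_config(config: RunConfig,
                             table: Optional[TypingTable] = None,
                             overrides: Optional[TypingTable] = None
                             ) -> tuple[list[PLIGraph], list[dict]]:
    """Parse every structure and build one graph per qualifying ligand.

    Failures are logged and recorded, never fatal per structure.
    """
    table = table or default_typing_table()
    if overrides is None:
        overrides = _load_overrides(config.overrides_path)
    graphs: list[PLIGraph] = []
    dropped: list[dict] = []
    for source, chain in config.structures:
        path = Path(source)
        sid = path.stem
        try:
            model = strip_hydrogens(parse_pdb(path.read_text(), sid))
        except (OSError, PDBParseError) as exc:
            logger.error("skipping %s: %s", source, exc)
            dropped.append({"structure": sid, "chain": chain, "reason": str(exc)})
            continue
        try:
            ligands = extract_ligands(model, chain)
        except KeyError as exc:
            dropped.append({"structure": sid, "chain": chain, "reason": str(exc)})
            continue
        if not ligands:
            dropped.append({"structure": sid, "chain": chain, "reason": "no ligand"})
            continue
        for ligand in ligands:
            g = build_pli_graph(model, chain, ligand, table, config.criteria, overrides)
            if g is None:
                dropped.append({"structure": sid, "chain": chain,
                                "ligand": ligand.instance_id, "reason": "no contacts"})
            else:
                graphs.append(g)
    return graphs, dropped


def run_project(config: RunConfig,
                table: Optional[TypingTable] = None,
                overrides: Optional[TypingTable] = None) -> ResultsBundle:
    """Execute the full pipeline; persists artifacts if output_dir is set."""
    graphs, dropped = build_graphs_from_config(config, table, overrides)
    if not graphs:
        raise RuntimeError("no interaction graphs survived; nothing to analyse")
    matrix = assemble_matrix(graphs, config.max_path_length)
    embedding = svd_reduce(matrix)
    n = len(graphs)
    k_range = config.k_range
    if k_range is None:
        from plimotif.clustering import default_k_range
        k_range = list(default_k_range(n))
    model = select_model(embedding, config.algorithm, config.metric, k_range, config.seed)

    motifs: dict[tuple[int, float], list[MotifGraph]] = {}
    by_group: dict[int, list[PLIGraph]] = {}
    for g in graphs:
        by_group.setdefault(model.labels[g.graph_id], []).append(g)
    for group in sorted(by_group):
        members = by_group[group]
        for fraction in config.support_fractions:
            mined = mine_frequent_subgraphs(members, fraction,
                                            max_edges=config.max_motif_edges,
                                            cluster_id=group)
            motifs[(group, fraction)] = filter_maximal(mined)

    embeddings: dict[str, list[MotifEmbedding]] = {}
    stats: dict[str, list[LigandAtomStat]] = {}
    counter = 0
    for (group, fraction), motif_list in sorted(motifs.items()):
        for m in motif_list:
            counter += 1
            m.motif_id = f"m{counter:04d}_g{group}_s{fraction:g}"
            embs = []
            for g in graphs:
                embs.extend(map_embeddings(m, g, graph_id=g.graph_id))
            for e in embs:
                e.motif_id = m.motif_id
            embeddings[m.motif_id] = embs
            stats[m.motif_id] = ligand_atom_stats(m, embs)

    bundle = ResultsBundle(config=config, graphs=graphs, matrix=matrix,
                           cluster_model=model, motifs=motifs,
                           embeddings=embeddings, stats=stats, dropped=dropped)
    if config.output_dir:
        save_bundle(bundle, Path(config.output_dir))
    return bundle


# --------------------------------------------------------------------------
# Analytic tables
# --------------------------------------------------------------------------

def patterns_table(bundle: ResultsBundle) -> pd.DataFrame:
    """Occurrence counts of maximal motifs by (group, support, motif size)."""
    rows = []
    for (group, fraction), motif_list in sorted(bundle.motifs.items()):
        sizes: dict[int, int] = {}
        for m in motif_list:
            sizes[m.size] = sizes.get(m.size, 0) + 1
        for size in sorted(sizes):
            rows.append({"group": group, "support_fraction": fraction,
                         "motif_size": size, "occurrences": sizes[size]})
    return pd.DataFrame(rows, columns=["group", "support_fraction",
                                       "motif_size", "occurrences"])


def histograms(bundle: ResultsBundle, facet: str = "interaction_type",
               by: str = "group") -> pd.DataFrame:
    """Counts of motif node types or motif edge interactions.

    facet: 'atom_type' counts each physicochemical type of each motif
    node; 'interaction_type' counts motif edges by class.  by: 'group' or
    'support' selects the grouping column.
    """
    if facet not in ("atom_type", "interaction_type"):
        raise ValueError(f"unknown facet {facet!r}")
    if by not in ("group", "support"):
        raise ValueError(f"unknown grouping {by!r}")
    counts: dict[tuple, int] = {}
    for (group, fraction), motif_list in bundle.motifs.items():
        key0 = group if by == "group" else fraction
        for m in motif_list:
            if facet == "interaction_type":
                for _u, _v, d in m.graph.edges(data=True):
                    counts[(key0, d["label"])] = counts.get((key0, d["label"]), 0) + 1
            else:
                for _n, d in m.graph.nodes(data=True):
                    type_part = d["label"].split(":", 1)[1]
                    for t in type_part.split(","):
                        if t:
                            counts[(key0, t)] = counts.get((key0, t), 0) + 1
    rows = [{by: k[0], facet: k[1], "count": v} for k, v in sorted(counts.items())]
    return pd.DataFrame(rows, columns=[by, facet, "count"])


def search_residue(bundle: ResultsBundle, query: str) -> list[tuple[str, str]]:
    """Case-insensitive substring search over residue name+number, ligand
    name, and atom name; returns (graph_id, node id) pairs."""
    q = query.strip().lower()
    hits = []
    for g in bundle.graphs:
        for n, d in g.graph.nodes(data=True):
            residue = f"{d['residue_name']}{d['residue_number']}".lower()
            if (q in residue or q in d["residue_name"].lower()
                    or q in d["atom_name"].lower()):
                hits.append((g.graph_id, n))
    return hits


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def _motif_to_json(m: MotifGraph) -> dict:
    return {
        "motif_id": m.motif_id,
        "cluster_id": m.cluster_id,
        "support_fraction": m.support_fraction,
        "support_count": m.support_count,
        "size": m.size,
        "n_edges": m.n_edges,
        "graph_ids": m.graph_ids,
        "nodes": [{"id": n, "label": d["label"]}
                  for n, d in sorted(m.graph.nodes(data=True))],
        "edges": sorted(({"source": min(u, v), "target": max(u, v), "label": d["label"]}
                         for u, v, d in m.graph.edges(data=True)),
                        key=lambda e: (e["source"], e["target"], e["label"])),
    }


def save_bundle(bundle: ResultsBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    for sub in ("graphs", "motifs"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for g in bundle.graphs:
        write_graphml(g, outdir / "graphs" / f"{g.graph_id}.graphml")
        (outdir / "graphs" / f"{g.graph_id}.json").write_text(
            json.dumps(graph_to_json(g), indent=1, sort_keys=True))
    bundle.matrix.to_csv(outdir / "feature_matrix.csv")

    model = bundle.cluster_model
    cluster_rows = [
        {"graph_id": g.graph_id, "structure_id": g.structure_id,
         "chain": g.chain_id, "ligand": g.ligand_name, "group": model.labels[g.graph_id]}
        for g in bundle.graphs
    ]
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)

    motif_index = []
    for (group, fraction), motif_list in sorted(bundle.motifs.items()):
        for m in motif_list:
            motif_index.append(_motif_to_json(m))
            import networkx as nx
            nx.write_graphml(m.graph, outdir / "motifs" / f"{m.motif_id}.graphml")
    (outdir / "motifs.json").write_text(json.dumps(motif_index, indent=1, sort_keys=True))

    emb_json = {
        mid: [
            {"graph_id": e.graph_id,
             "node_map": {str(k): v for k, v in e.node_map.items()}}
            for e in embs
        ]
        for mid, embs in sorted(bundle.embeddings.items())
    }
    (outdir / "embeddings.json").write_text(json.dumps(emb_json, indent=1, sort_keys=True))

    stat_rows = [
        {"motif_id": mid, "ligand_atom_name": s.ligand_atom_name,
         "interaction_count": s.interaction_count, "graph_count": s.graph_count}
        for mid, stats in sorted(bundle.stats.items()) for s in stats
    ]
    pd.DataFrame(stat_rows, columns=["motif_id", "ligand_atom_name",
                                     "interaction_count", "graph_count"]
                 ).to_csv(outdir / "ligand_atom_stats.csv", index=False)

    patterns_table(bundle).to_csv(outdir / "patterns_table.csv", index=False)
    histograms(bundle, "interaction_type", "group").to_csv(
        outdir / "histogram_interactions.csv", index=False)
    histograms(bundle, "atom_type", "group").to_csv(
        outdir / "histogram_atom_types.csv", index=False)
    if bundle.dropped:
        pd.DataFrame(bundle.dropped).to_csv(outdir / "dropped.csv", index=False)

    from importlib.metadata import version as _pkg_version
    try:
        pkg_version = _pkg_version("plimotif")
    except Exception:
        pkg_version = "unknown"
    metadata = {
        "config": bundle.config.to_dict(),
        "version": pkg_version,
        "n_graphs": len(bundle.graphs),
        "chosen_k": model.k,
        "n_groups": model.n_groups,
        "score": model.score,
        "algorithm": model.algorithm,
        "metric": model.metric,
        "svd_rank": None,
        "n_motifs": sum(len(v) for v in bundle.motifs.values()),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=1, sort_keys=True))


def _motif_from_json(d: dict) -> MotifGraph:
    import networkx as nx
    g = nx.MultiGraph()
    for node in d["nodes"]:
        g.add_node(node["id"], label=node["label"])
    for e in d["edges"]:
        g.add_edge(e["source"], e["target"], label=e["label"])
    return MotifGraph(graph=g, support_count=d["support_count"],
                      support_fraction=d["support_fraction"],
                      graph_ids=list(d["graph_ids"]),
                      cluster_id=d["cluster_id"], motif_id=d["motif_id"])


def load_bundle(outdir: Path, config: Optional[RunConfig] = None) -> ResultsBundle:
    """Reconstruct a ResultsBundle from a saved run directory.

    The reload reproduces every analytic table bit-identically; the
    cluster-model score is taken from run_metadata.
    """
    outdir = Path(outdir)
    graphs = [
        graph_from_json(json.loads(p.read_text()))
        for p in sorted((outdir / "graphs").glob("*.json"))
    ]
    matrix = FeatureMatrix.from_csv(outdir / "feature_matrix.csv")
    meta = json.loads((outdir / "run_metadata.json").read_text())
    clusters = pd.read_csv(outdir / "clusters.csv")
    labels = dict(zip(clusters["graph_id"], clusters["group"].astype(int)))
    model = ClusterModel(algorithm=meta["algorithm"], k=meta["chosen_k"],
                         labels=labels, metric=meta["metric"],
                         score=meta["score"], seed=meta["config"]["seed"])
    motifs: dict[tuple[int, float], list[MotifGraph]] = {}
    for d in json.loads((outdir / "motifs.json").read_text()):
        m = _motif_from_json(d)
        motifs.setdefault((m.cluster_id, m.support_fraction), []).append(m)
    emb_json = json.loads((outdir / "embeddings.json").read_text())
    embeddings = {
        mid: [MotifEmbedding(motif_id=mid, graph_id=e["graph_id"],
                             node_map={int(k): v for k, v in e["node_map"].items()},
                             edge_map={})
              for e in embs]
        for mid, embs in emb_json.items()
    }
    stats: dict[str, list[LigandAtomStat]] = {}
    stats_path = outdir / "ligand_atom_stats.csv"
    if stats_path.exists() and stats_path.stat().st_size > 0:
        df = pd.read_csv(stats_path)
        for row in df.itertuples(index=False):
            stats.setdefault(row.motif_id, []).append(LigandAtomStat(
                motif_id=row.motif_id, ligand_atom_name=row.ligand_atom_name,
                interaction_count=int(row.interaction_count),
                graph_count=int(row.graph_count)))
    if config is None:
        c = meta["config"]
        config = RunConfig(
            structures=[tuple(s) for s in c["structures"]],
            criteria=DistanceCriteria.from_dict(c["criteria"]),
            algorithm=c["algorithm"], metric=c["metric"], k_range=c["k_range"],
            seed=c["seed"], support_fractions=tuple(c["support_fractions"]),
            max_path_length=c["max_path_length"],
            max_motif_edges=c["max_motif_edges"],
            output_dir=str(outdir), overrides_path=c["overrides_path"])
    return ResultsBundle(config=config, graphs=graphs, matrix=matrix,
                         cluster_model=model, motifs=motifs,
                         embeddings=embeddings, stats=stats)
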