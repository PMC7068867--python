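"""Typed protein-ligand interaction graphs.

A contact exists between a protein atom and a ligand atom when their
Euclidean distance is at most a cutoff; each contact is classified into
zero or more of five non-covalent interaction classes by the
physicochemical types of its endpoints and a per-class distance window:

===================  ==============================  ==========  ==========
interaction          atom-type condition              min (Å)     max (Å)
===================  ==============================  ==========  ==========
aromatic_stacking    two aromatic atoms               1.5         3.5
hydrogen_bond        an acceptor and a donor          2.0         3.0
hydrophobic          two hydrophobic atoms            2.0         3.8
repulsive            two like-charged atoms           2.0         6.0
salt_bridge          two opposite-charged atoms       2.0         6.0
===================  ==============================  ==========  ==========

Both window ends are inclusive.  A pair satisfying several conditions at
once produces one parallel edge per satisfied class, so no information is
lost downstream.  The resulting graph is bipartite by construction: only
cross (protein x ligand) pairs are ever examined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from plimotif.structure_io import LigandInstance, StructureModel, protein_atoms
from plimotif.atom_typing import (
    TypedAtom,
    TypingTable,
    type_ligand_atoms,
    type_protein_atoms,
)

logger = logging.getLogger(__name__)

#: Closed vocabulary of interaction classes, canonical order.
INTERACTION_TYPES = (
    "aromatic_stacking",
    "hydrogen_bond",
    "hydrophobic",
    "repulsive",
    "salt_bridge",
)


@dataclass(frozen=True)
class DistanceCriteria:
    """Per-class [min, max] distance windows in Å (both ends inclusive)."""

    windows: tuple[tuple[str, float, float], ...] = (
        ("aromatic_stacking", 1.5, 3.5),
        ("hydrogen_bond", 2.0, 3.0),
        ("hydrophobic", 2.0, 3.8),
        ("repulsive", 2.0, 6.0),
        ("salt_bridge", 2.0, 6.0),
    )

    def __post_init__(self):
        names = [n for n, _, _ in self.windows]
        if sorted(names) != sorted(INTERACTION_TYPES):
            raise ValueError(f"criteria must cover exactly {INTERACTION_TYPES}, got {names}")
        for name, lo, hi in self.windows:
            if not (0 < lo < hi):
                raise ValueError(f"invalid window for {name}: [{lo}, {hi}]")

    def window(self, interaction: str) -> tuple[float, float]:
        for name, lo, hi in self.windows:
            if name == interaction:
                return lo, hi
        raise KeyError(interaction)

    @property
    def global_cutoff(self) -> float:
        return max(hi for _, _, hi in self.windows)

    def replace(self, **updates: tuple[float, float]) -> "DistanceCriteria":
        new = []
        for name, lo, hi in self.windows:
            if name in updates:
                lo, hi = updates[name]
            new.append((name, lo, hi))
        unknown = set(updates) - set(INTERACTION_TYPES)
        if unknown:
            raise KeyError(f"unknown interaction types: {sorted(unknown)}")
        return DistanceCriteria(windows=tuple(new))

    def to_dict(self) -> dict[str, list[float]]:
        return {name: [lo, hi] for name, lo, hi in self.windows}

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceCriteria":
        return cls(windows=tuple((name, float(lo), float(hi))
                                 for name, (lo, hi) in sorted(d.items())))


DEFAULT_CRITERIA = DistanceCriteria()


@dataclass(frozen=True)
class InteractionEdge:
    protein_atom: TypedAtom
    ligand_atom: TypedAtom
    interaction: str
    distance: float


@dataclass
class PLIGraph:
    """Labeled bipartite graph of one (chain, ligand instance) interface.

    ``graph`` is a :class:`networkx.MultiGraph`: node ids are
    ``P<serial>``/``L<serial>`` strings, node attributes carry provenance
    (role, residue, chain, atom name) plus ``label`` (the mining label:
    role prefix + sorted type set), and parallel edges carry one
    interaction class each in their ``label`` attribute.
    """

    graph_id: str
    structure_id: str
    chain_id: str
    ligand_name: str
    ligand_residue_number: int
    graph: nx.MultiGraph

    @property
    def protein_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == "protein"]

    @property
    def ligand_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == "ligand"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_bipartite(self) -> bool:
        return all(self.graph.nodes[u]["role"] != self.graph.nodes[v]["role"]
                   for u, v, _ in self.graph.edges(keys=True))


def compute_contacts(protein: list[TypedAtom], ligand: list[TypedAtom],
                     global_cutoff: float) -> list[tuple[int, int, float]]:
    """All cross pairs within the cutoff, as (protein idx, ligand idx, distance).

    Distance comparison is inclusive (``<=``).  Uses a k-d tree over the
    ligand atoms; equivalent to the brute-force double loop.
    """
    if not protein or not ligand:
        return []
    pcoords = np.array([t.atom.coord for t in protein])
    lcoords = np.array([t.atom.coord for t in ligand])
    tree = cKDTree(lcoords)
    out: list[tuple[int, int, float]] = []
    for i, row in enumerate(pcoords):
        for j in tree.query_ball_point(row, r=global_cutoff):
            d = float(np.linalg.norm(row - lcoords[j]))
            if d <= global_cutoff:
                out.append((i, j, d))
    return out


def classify_interactions(types_i: frozenset[str] | set[str],
                          types_j: frozenset[str] | set[str],
                          distance: float,
                          criteria: DistanceCriteria = DEFAULT_CRITERIA) -> set[str]:
    """Interaction classes satisfied by a typed atom pair at a distance.

    Symmetric in the two type sets; returns possibly several classes
    (parallel edges downstream).
    """
    ti, tj = set(types_i), set(types_j)
    satisfied: set[str] = set()

    def in_window(name: str) -> bool:
        lo, hi = criteria.window(name)
        return lo <= distance <= hi

    if "aromatic" in ti and "aromatic" in tj and in_window("aromatic_stacking"):
        satisfied.add("aromatic_stacking")
    if (("acceptor" in ti and "donor" in tj) or ("donor" in ti and "acceptor" in tj)) \
            and in_window("hydrogen_bond"):
        satisfied.add("hydrogen_bond")
    if "hydrophobic" in ti and "hydrophobic" in tj and in_window("hydrophobic"):
        satisfied.add("hydrophobic")
    if (("negative" in ti and "negative" in tj) or ("positive" in ti and "positive" in tj)) \
            and in_window("repulsive"):
        satisfied.add("repulsive")
    if (("negative" in ti and "positive" in tj) or ("positive" in ti and "negative" in tj)) \
            and in_window("salt_bridge"):
        satisfied.add("salt_bridge")
    return satisfied


def _node_id(t: TypedAtom) -> str:
    prefix = "P" if t.molecule_role == "protein" else "L"
    return f"{prefix}{t.atom.serial}"


def _add_node(g: nx.MultiGraph, t: TypedAtom) -> str:
    nid = _node_id(t)
    if nid not in g:
        a = t.atom
        g.add_node(
            nid,
            role=t.molecule_role,
            residue_name=a.residue_name,
            residue_number=a.residue_number,
            chain=a.chain_id,
            atom_name=a.atom_name,
            serial=a.serial,
            types=",".join(t.sorted_types),
            label=t.mining_label,
        )
    return nid


def build_pli_graph(model: StructureModel, chain_id: str, ligand: LigandInstance,
                    table: TypingTable,
                    criteria: DistanceCriteria = DEFAULT_CRITERIA,
                    overrides: Optional[TypingTable] = None) -> Optional[PLIGraph]:
    """Assemble the bipartite interaction graph for one (chain, ligand) pair.

    Returns ``None`` (with a logged reason) when no classified edge exists.
    Isolated atoms never enter the graph.
    """
    prot_typed = type_protein_atoms(protein_atoms(model, chain_id), table)
    lig_typed = type_ligand_atoms(ligand, overrides)
    prot_typed = [t for t in prot_typed if t.types]
    lig_typed = [t for t in lig_typed if t.types]

    g = nx.MultiGraph()
    for i, j, d in compute_contacts(prot_typed, lig_typed, criteria.global_cutoff):
        p, l = prot_typed[i], lig_typed[j]
        for interaction in sorted(classify_interactions(p.types, l.types, d, criteria)):
            pn = _add_node(g, p)
            ln = _add_node(g, l)
            g.add_edge(pn, ln, label=interaction, interaction=interaction,
                       distance=round(d, 2))
    graph_id = f"{model.structure_id}.{chain_id}.{ligand.instance_id}"
    if g.number_of_edges() == 0:
        logger.info("no classified contacts for %s; graph dropped", graph_id)
        return None
    return PLIGraph(
        graph_id=graph_id,
        structure_id=model.structure_id,
        chain_id=chain_id,
        ligand_name=ligand.ligand_name,
        ligand_residue_number=ligand.residue_number,
        graph=g,
    )


def build_all_graphs(model: StructureModel, chain_id: str, table: TypingTable,
                     criteria: DistanceCriteria = DEFAULT_CRITERIA,
                     overrides: Optional[TypingTable] = None) -> list[PLIGraph]:
    """One graph per qualifying ligand instance on the chain."""
    from plimotif.structure_io import extract_ligands

    graphs = []
    for ligand in extract_ligands(model, chain_id):
        g = build_pli_graph(model, chain_id, ligand, table, criteria, overrides)
        if g is not None:
            graphs.append(g)
    return graphs


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def graph_to_json(pli: PLIGraph) -> dict:
    return {
        "graph_id": pli.graph_id,
        "structure_id": pli.structure_id,
        "chain_id": pli.chain_id,
        "ligand_name": pli.ligand_name,
        "ligand_residue_number": pli.ligand_residue_number,
        "nodes": [
            {"id": n, **{k: d[k] for k in ("role", "residue_name", "residue_number",
                                           "chain", "atom_name", "serial", "types", "label")}}
            for n, d in sorted(pli.graph.nodes(data=True))
        ],
        "edges": sorted(
            ({"source": min(u, v), "target": max(u, v),
              "interaction": d["interaction"], "distance": d["distance"]}
             for u, v, d in pli.graph.edges(data=True)),
            key=lambda e: (e["source"], e["target"], e["interaction"]),
        ),
    }


def graph_from_json(d: dict) -> PLIGraph:
    g = nx.MultiGraph()
    for node in d["nodes"]:
        nid = node.pop("id")
        g.add_node(nid, **node)
    for e in d["edges"]:
        g.add_edge(e["source"], e["target"], label=e["interaction"],
                   interaction=e["interaction"], distance=e["distance"])
    return PLIGraph(
        graph_id=d["graph_id"],
        structure_id=d["structure_id"],
        chain_id=d["chain_id"],
        ligand_name=d["ligand_name"],
        ligand_residue_number=d["ligand_residue_number"],
        graph=g,
    )


def write_graphml(pli: PLIGraph, path) -> None:
    nx.write_graphml(pli.graph, path)
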