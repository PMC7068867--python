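"""Synthetic inputs with known ground truth, plus brute-force oracles.

Two generators cover the pipeline's input formats:

* :func:`make_complex` writes a PDB-format micro-complex whose atom
  coordinates realize a chosen list of interface interactions exactly, so
  the graph builder's output is known by construction.  The protein side
  uses real residue/atom names (the typing table applies unmodified); the
  ligand side uses a synthetic het code plus an override typing table.
* :func:`make_planted_dataset` draws labeled bipartite multigraphs with a
  motif planted in a controlled fraction of them and seeded noise edges.

The brute-force enumerators (:func:`brute_force_fsm`,
:func:`brute_force_embeddings`) are deliberately naive -- exhaustive
search with permutation-based canonical forms -- and exist to check the
gSpan miner and the VF2 mapper on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from plimotif.atom_typing import TypingTable
from plimotif.interaction_graph import PLIGraph
from plimotif.motif_mining import MotifGraph, _as_multigraph

#: Synthetic het code used by generated complexes.
SYNTHETIC_LIGAND_CODE = "LIG"

_DISTANCE_TOL = 1e-3


# ==========================================================================
# PDB micro-complex generator
# ==========================================================================

@dataclass(frozen=True)
class AtomSpec:
    residue_name: str
    residue_number: int
    atom_name: str
    molecule_role: str  # "protein" | "ligand"
    position: tuple[float, float, float]
    element: Optional[str] = None

    @property
    def inferred_element(self) -> str:
        return self.element or self.atom_name[0].upper()


@dataclass
class ComplexSpec:
    structure_id: str
    chain_id: str
    atoms: list[AtomSpec]
    # (index_a, index_b, interaction, target distance in Å)
    intended: list[tuple[int, int, str, float]] = field(default_factory=list)


def make_complex(spec: ComplexSpec) -> str:
    """PDB text realizing the spec; distance targets are verified exactly."""
    for ia, ib, interaction, target in spec.intended:
        pa = np.array(spec.atoms[ia].position)
        pb = np.array(spec.atoms[ib].position)
        d = float(np.linalg.norm(pa - pb))
        if abs(d - target) > _DISTANCE_TOL:
            raise ValueError(
                f"unsatisfiable spec: atoms {ia}-{ib} ({interaction}) realize "
                f"{d:.4f} Å, target {target:.4f} Å")
    n_ligand = sum(1 for a in spec.atoms if a.molecule_role == "ligand")
    if n_ligand < 6:
        raise ValueError(f"ligand part has {n_ligand} atoms; needs >= 6")
    lines = []
    for serial, a in enumerate(spec.atoms, start=1):
        rec = "ATOM  " if a.molecule_role == "protein" else "HETATM"
        name = a.atom_name
        element = a.inferred_element
        if len(name) < 4 and len(element) == 1:
            name = " " + name
        x, y, z = a.position
        lines.append(
            f"{rec}{serial:>5d} {name:<4s} {a.residue_name:>3s} "
            f"{spec.chain_id:1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element.upper():>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


_TYPE_LETTER = {"acceptor": "A", "aromatic": "R", "donor": "D",
                "hydrophobic": "H", "negative": "N", "positive": "P"}

# Unit directions used when several protein atoms share one ligand atom.
_DIRECTIONS = [(0.0, 1.0, 0.0), (0.0, -1.0, 0.0), (0.0, 0.0, 1.0),
               (0.0, 0.0, -1.0), (0.0, 0.7071, 0.7071), (0.0, -0.7071, 0.7071)]


@dataclass(frozen=True)
class InterfaceContact:
    """One engineered protein-ligand contact for :func:`make_profile_complex`.

    When ``ligand_atom`` names an atom used by an earlier contact of the
    same complex, that atom is shared, producing a connected multi-edge
    neighbourhood (the route to engineered connected motifs).  Left unset,
    the ligand atom is auto-named from its type set plus the slot index,
    so override tables from different complexes merge without collisions.
    """

    protein_residue: str       # e.g. "LEU"
    protein_atom: str          # e.g. "CD1"
    ligand_types: tuple[str, ...]  # override type set for the ligand atom
    distance: float            # realized Euclidean distance in Å
    ligand_atom: Optional[str] = None

    def auto_name(self, slot: int) -> str:
        code = "".join(_TYPE_LETTER[t] for t in sorted(self.ligand_types)) or "X"
        return f"{code[:3]}{slot + 1}"


def make_profile_complex(structure_id: str,
                         contacts: Sequence[InterfaceContact],
                         chain_id: str = "A") -> tuple[str, TypingTable]:
    """A complex realizing exactly the given contacts, plus its override table.

    Each new ligand atom occupies its own spatial slot 25 Å from the
    others, so no unintended cross pair falls inside any criteria window;
    protein atoms attached to a shared ligand atom fan out in distinct
    directions.  Filler ligand atoms (empty type set) pad the ligand to
    the six-atom minimum.
    """
    atoms: list[AtomSpec] = []
    intended: list[tuple[int, int, str, float]] = []
    overrides = TypingTable()
    lig_resnum = 900
    lig_atom_index: dict[str, int] = {}      # ligand atom name -> index in atoms
    attached: dict[str, int] = {}            # ligand atom name -> protein count
    n_slots = 0
    for i, c in enumerate(contacts):
        lig_name = c.ligand_atom or c.auto_name(n_slots)
        if lig_name in lig_atom_index:
            existing = overrides.lookup(SYNTHETIC_LIGAND_CODE, lig_name)
            if existing != frozenset(c.ligand_types):
                raise ValueError(f"contact {i}: shared ligand atom {lig_name!r} "
                                 f"redeclared with different types")
            l_idx = lig_atom_index[lig_name]
        else:
            base = (25.0 * n_slots, 0.0, 0.0)
            n_slots += 1
            l_idx = len(atoms)
            atoms.append(AtomSpec(SYNTHETIC_LIGAND_CODE, lig_resnum, lig_name,
                                  "ligand", base, element="C"))
            lig_atom_index[lig_name] = l_idx
            attached[lig_name] = 0
            overrides.add(SYNTHETIC_LIGAND_CODE, lig_name, c.ligand_types)
        direction = _DIRECTIONS[attached[lig_name] % len(_DIRECTIONS)]
        attached[lig_name] += 1
        lx, ly, lz = atoms[l_idx].position
        pos = (lx + direction[0] * c.distance,
               ly + direction[1] * c.distance,
               lz + direction[2] * c.distance)
        p_idx = len(atoms)
        atoms.append(AtomSpec(c.protein_residue, i + 1, c.protein_atom,
                              "protein", pos))
        intended.append((p_idx, l_idx, "contact", c.distance))
    for k in range(max(0, 6 - len(lig_atom_index))):
        name = f"X9{k}"
        atoms.append(AtomSpec(SYNTHETIC_LIGAND_CODE, lig_resnum, name, "ligand",
                              (-100.0 - 25.0 * k, -100.0, -100.0), element="C"))
        overrides.add(SYNTHETIC_LIGAND_CODE, name, [])
    spec = ComplexSpec(structure_id=structure_id, chain_id=chain_id,
                       atoms=atoms, intended=intended)
    return make_complex(spec), overrides


def merge_typing_tables(tables: Iterable[TypingTable]) -> TypingTable:
    """Union of override tables; conflicting redefinitions are an error."""
    merged = TypingTable()
    for t in tables:
        for (res, atom), types in t._entries.items():
            existing = merged.get(res, atom)
            if existing is not None and existing != types:
                raise ValueError(f"conflicting override for ({res}, {atom})")
            merged.add(res, atom, types)
    return merged


def make_profile_dataset(families: dict[str, Sequence[InterfaceContact]],
                         n_per_family: int = 3,
                         chain_id: str = "A",
                         vary: bool = True
                         ) -> tuple[list[tuple[str, str, str]], TypingTable]:
    """A multi-complex dataset of engineered interaction-profile families.

    Returns ([(structure_id, pdb_text, chain)], merged override table).
    With ``vary`` set, complexes after the first in each family gain one
    benign extra hydrogen-bond contact so feature rows differ within a
    family without touching the shared profile.
    """
    entries = []
    tables = []
    for fam, contacts in families.items():
        for i in range(n_per_family):
            cs = list(contacts)
            if vary and i > 0:
                cs.append(InterfaceContact("GLY", "O", ("donor",),
                                           round(2.4 + 0.1 * i, 2)))
            sid = f"fam{fam}{i}"
            text, ov = make_profile_complex(sid, cs, chain_id)
            entries.append((sid, text, chain_id))
            tables.append(ov)
    return entries, merge_typing_tables(tables)


# ==========================================================================
# Planted-motif graph datasets
# ==========================================================================

@dataclass
class PlantedMotifSpec:
    """Bipartite labeled multigraph collection with a planted motif."""

    motif: nx.MultiGraph  # nodes with 'label' ("P:..."/"L:..."), edges with 'label'
    n_graphs: int = 20
    plant_fraction: float = 0.7
    noise_edges: int = 3
    protein_labels: tuple[str, ...] = ("P:hydrophobic", "P:acceptor", "P:donor,positive")
    ligand_labels: tuple[str, ...] = ("L:hydrophobic", "L:acceptor,negative", "L:donor")
    edge_labels: tuple[str, ...] = ("hydrophobic", "hydrogen_bond", "salt_bridge")
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.plant_fraction <= 1):
            raise ValueError(f"plant_fraction must be in (0, 1], got {self.plant_fraction}")


def default_planted_motif() -> nx.MultiGraph:
    """A 5-node bipartite motif: P-L-P-L-P path with mixed edge labels."""
    m = nx.MultiGraph()
    labels = ["P:acceptor,negative", "L:donor,positive", "P:acceptor,negative",
              "L:hydrophobic", "P:hydrophobic"]
    edges = [("salt_bridge", 0, 1), ("salt_bridge", 1, 2),
             ("hydrophobic", 3, 4)]
    for i, lab in enumerate(labels):
        m.add_node(i, label=lab)
    m.add_edge(0, 1, label="salt_bridge")
    m.add_edge(1, 2, label="salt_bridge")
    m.add_edge(2, 3, label="hydrogen_bond")
    m.add_edge(3, 4, label="hydrophobic")
    return m


def _contains_pattern(pattern: nx.MultiGraph, host: nx.MultiGraph) -> bool:
    return bool(brute_force_embeddings(pattern, host, max_results=1))


def make_planted_dataset(spec: PlantedMotifSpec) -> list[nx.MultiGraph]:
    """Draw the dataset; exactly round(plant_fraction * n) graphs contain
    the motif, the rest are verified motif-free (noise resampled if not)."""
    rng = np.random.default_rng(spec.seed)
    n_plant = round(spec.plant_fraction * spec.n_graphs)
    plant_idx = set(rng.choice(spec.n_graphs, size=n_plant, replace=False).tolist())
    graphs = []
    for i in range(spec.n_graphs):
        for attempt in range(50):
            g = _draw_graph(spec, rng, planted=i in plant_idx)
            if i in plant_idx or not _contains_pattern(spec.motif, g):
                break
        else:
            raise RuntimeError("could not draw a motif-free noise graph in 50 tries; "
                               "enlarge the label alphabet")
        g.graph["graph_id"] = f"synth_{spec.seed}_{i}"
        graphs.append(g)
    return graphs


def _draw_graph(spec: PlantedMotifSpec, rng: np.random.Generator,
                planted: bool) -> nx.MultiGraph:
    g = nx.MultiGraph()
    next_id = 0

    def new_node(label: str) -> int:
        nonlocal next_id
        g.add_node(next_id, label=label)
        next_id += 1
        return next_id - 1

    if planted:
        mapping = {n: new_node(d["label"]) for n, d in spec.motif.nodes(data=True)}
        for u, v, d in spec.motif.edges(data=True):
            g.add_edge(mapping[u], mapping[v], label=d["label"])
    # Noise: bipartite edges between (possibly fresh) P-side and L-side nodes.
    for _ in range(spec.noise_edges):
        def pick(side_labels: tuple[str, ...]) -> int:
            existing = [n for n, d in g.nodes(data=True)
                        if d["label"].startswith(side_labels[0][0])]
            if existing and rng.random() < 0.5:
                return int(rng.choice(existing))
            return new_node(str(rng.choice(list(side_labels))))

        p = pick(spec.protein_labels)
        l = pick(spec.ligand_labels)
        elabel = str(rng.choice(list(spec.edge_labels)))
        if any(d["label"] == elabel for d in g[p][l].values()) if g.has_edge(p, l) else False:
            continue  # never duplicate a parallel same-label edge
        g.add_edge(p, l, label=elabel)
    if g.number_of_edges() == 0:
        # Keep every graph non-empty.
        p = new_node(str(rng.choice(list(spec.protein_labels))))
        l = new_node(str(rng.choice(list(spec.ligand_labels))))
        g.add_edge(p, l, label=str(rng.choice(list(spec.edge_labels))))
    return g


def random_labeled_dataset(n_graphs: int, seed: int,
                           max_nodes: int = 8,
                           n_edges: tuple[int, int] = (2, 6)) -> list[nx.MultiGraph]:
    """Small random bipartite labeled multigraphs for oracle-agreement tests."""
    spec = PlantedMotifSpec(motif=default_planted_motif(), n_graphs=1, seed=seed)
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_graphs):
        g = nx.MultiGraph()
        n_p = int(rng.integers(1, max_nodes // 2 + 1))
        n_l = int(rng.integers(1, max_nodes - n_p + 1))
        for j in range(n_p):
            g.add_node(j, label=str(rng.choice(list(spec.protein_labels))))
        for j in range(n_l):
            g.add_node(n_p + j, label=str(rng.choice(list(spec.ligand_labels))))
        target_edges = int(rng.integers(n_edges[0], n_edges[1] + 1))
        for _ in range(target_edges * 3):
            if g.number_of_edges() >= target_edges:
                break
            p = int(rng.integers(0, n_p))
            l = n_p + int(rng.integers(0, n_l))
            elabel = str(rng.choice(list(spec.edge_labels)))
            dup = g.has_edge(p, l) and any(
                d["label"] == elabel for d in g[p][l].values())
            if not dup:
                g.add_edge(p, l, label=elabel)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_edges() == 0:
            g.add_node(0, label=spec.protein_labels[0])
            g.add_node(1, label=spec.ligand_labels[0])
            g.add_edge(0, 1, label=spec.edge_labels[0])
        g.graph["graph_id"] = f"rand_{seed}_{i}"
        graphs.append(g)
    return graphs


# ==========================================================================
# Brute-force oracles
# ==========================================================================

def canonical_certificate(graph: Union[nx.MultiGraph, MotifGraph],
                          max_nodes: int = 8) -> tuple:
    """Permutation-minimal canonical form; equal iff isomorphic.

    Exhaustive over node permutations -- only for small patterns.
    """
    g = graph.graph if isinstance(graph, MotifGraph) else graph
    nodes = list(g.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(f"certificate limited to {max_nodes} nodes, got {len(nodes)}")
    labels = {n: g.nodes[n]["label"] for n in nodes}
    edges = [(u, v, d["label"]) for u, v, d in g.edges(data=True)]
    best = None
    for perm in itertools.permutations(nodes):
        pos = {n: i for i, n in enumerate(perm)}
        cand = (
            tuple(labels[n] for n in perm),
            tuple(sorted((min(pos[u], pos[v]), max(pos[u], pos[v]), el)
                         for u, v, el in edges)),
        )
        if best is None or cand < best:
            best = cand
    return best


def _connected_edge_subsets(g: nx.MultiGraph, max_nodes: int) -> list[list]:
    """All connected edge-subsets spanning at most ``max_nodes`` nodes."""
    edges = [(u, v, k) for u, v, k in g.edges(keys=True)]
    incident: dict = {}
    for e in edges:
        incident.setdefault(e[0], set()).add(e)
        incident.setdefault(e[1], set()).add(e)
    seen: set[frozenset] = set()
    out: list[list] = []
    frontier = [frozenset([e]) for e in edges]
    seen.update(frontier)
    while frontier:
        new_frontier = []
        for subset in frontier:
            nodes = set()
            for u, v, _ in subset:
                nodes.update((u, v))
            out.append(sorted(subset))
            adjacent = set()
            for n in nodes:
                adjacent |= incident[n]
            for e in adjacent - subset:
                grown_nodes = nodes | {e[0], e[1]}
                if len(grown_nodes) > max_nodes:
                    continue
                grown = subset | {e}
                if grown not in seen:
                    seen.add(grown)
                    new_frontier.append(grown)
        frontier = new_frontier
    return out


def _edge_subset_to_graph(g: nx.MultiGraph, subset) -> nx.MultiGraph:
    sub = nx.MultiGraph()
    for u, v, k in subset:
        for n in (u, v):
            if n not in sub:
                sub.add_node(n, label=g.nodes[n]["label"])
        sub.add_edge(u, v, label=g[u][v][k]["label"])
    return sub


def brute_force_fsm(graphs: Sequence[Union[PLIGraph, nx.MultiGraph]],
                    min_support_count: int,
                    max_size: int = 6) -> dict[tuple, int]:
    """Exhaustive frequent-connected-subgraph enumeration.

    Returns {canonical certificate: support count} for every connected
    subgraph of at most ``max_size`` nodes occurring in at least
    ``min_support_count`` graphs.  Guarded to tiny inputs (test oracle).
    """
    if max_size > 6:
        raise ValueError(f"brute-force oracle limited to max_size 6, got {max_size}")
    mgs = [_as_multigraph(g) for g in graphs]
    for g in mgs:
        if g.number_of_nodes() > 10:
            raise ValueError("brute-force oracle limited to graphs of <= 10 nodes")
    support: dict[tuple, int] = {}
    for g in mgs:
        certs = {canonical_certificate(_edge_subset_to_graph(g, subset))
                 for subset in _connected_edge_subsets(g, max_size)}
        for c in certs:
            support[c] = support.get(c, 0) + 1
    return {c: s for c, s in support.items() if s >= min_support_count}


def brute_force_embeddings(pattern: Union[nx.MultiGraph, MotifGraph],
                           graph: Union[PLIGraph, nx.MultiGraph],
                           max_results: Optional[int] = None) -> list[dict]:
    """All injective label-preserving maps pattern -> graph, one per
    node-image set (automorphic re-labelings collapsed)."""
    p = pattern.graph if isinstance(pattern, MotifGraph) else pattern
    g = _as_multigraph(graph)
    if g.number_of_nodes() > 12:
        raise ValueError("brute-force embedding oracle limited to <= 12-node graphs")
    pnodes = list(p.nodes)
    candidates = {
        n: [m for m in g.nodes if g.nodes[m]["label"] == p.nodes[n]["label"]]
        for n in pnodes
    }

    def edges_ok(assign: dict) -> bool:
        for u, v in {(min(a, b), max(a, b)) for a, b, _ in p.edges(keys=True)}:
            gu, gv = assign[u], assign[v]
            if not g.has_edge(gu, gv):
                return False
            need = [d["label"] for d in p[u][v].values()]
            have = [d["label"] for d in g[gu][gv].values()]
            counts: dict[str, int] = {}
            for lab in have:
                counts[lab] = counts.get(lab, 0) + 1
            for lab in need:
                if counts.get(lab, 0) == 0:
                    return False
                counts[lab] -= 1
        return True

    results: list[dict] = []
    seen_images: set[frozenset] = set()

    def assign(idx: int, current: dict, used: set) -> bool:
        if max_results is not None and len(results) >= max_results:
            return True
        if idx == len(pnodes):
            if edges_ok(current):
                image = frozenset(current.values())
                if image not in seen_images:
                    seen_images.add(image)
                    results.append(dict(current))
            return False
        n = pnodes[idx]
        for m in candidates[n]:
            if m in used:
                continue
            current[n] = m
            used.add(m)
            if assign(idx + 1, current, used):
                return True
            used.remove(m)
            del current[n]
        return False

    assign(0, {}, set())
    return results
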