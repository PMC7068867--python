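"""Frequent-subgraph mining of interface graphs and motif mapping.

The miner is gSpan: patterns are grown by rightmost extension of DFS
codes, each pattern is explored exactly once via the minimal-DFS-code
canonicality test, and support (the number of dataset graphs containing
the pattern) is anti-monotone under extension, which prunes the search.
Graphs here are undirected labeled multigraphs -- one atom pair may carry
several parallel edges, one per satisfied interaction class -- so DFS
codes track concrete edge identities and a backward extension may revisit
a node pair through a second, differently-labeled edge.

After mining, only maximal motifs are kept (a motif contained in another
reported motif of the same run adds nothing), and each motif is mapped
back onto every input graph with VF2 subgraph monomorphism to produce
explicit node/edge correspondences and per-ligand-atom contact statistics.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
from networkx.algorithms import isomorphism as iso

from plimotif.interaction_graph import PLIGraph

logger = logging.getLogger(__name__)

#: Default support sweep, matching a 0.1..1.0 step-0.1 schedule.
DEFAULT_SUPPORT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))

#: Per-(motif, graph) cap on enumerated embeddings (symmetry explosions).
MAX_EMBEDDINGS_PER_GRAPH = 10_000


# ==========================================================================
# Mining input representation
# ==========================================================================

class _MinedGraph:
    """Compact adjacency form of one labeled multigraph."""

    __slots__ = ("gid", "node_ids", "labels", "adj", "edges")

    def __init__(self, gid: str, g: nx.MultiGraph):
        self.gid = gid
        self.node_ids = sorted(g.nodes)
        index = {n: i for i, n in enumerate(self.node_ids)}
        self.labels = [str(g.nodes[n]["label"]) for n in self.node_ids]
        self.adj: list[list[tuple[int, int, str]]] = [[] for _ in self.node_ids]
        self.edges: list[tuple[int, int, str]] = []
        for u, v, d in sorted(g.edges(data=True),
                              key=lambda e: (str(e[0]), str(e[1]), str(e[2].get("label")))):
            eid = len(self.edges)
            iu, iv = index[u], index[v]
            label = str(d["label"])
            self.edges.append((iu, iv, label))
            self.adj[iu].append((eid, iv, label))
            self.adj[iv].append((eid, iu, label))


def _as_multigraph(g: Union[PLIGraph, nx.MultiGraph]) -> nx.MultiGraph:
    return g.graph if isinstance(g, PLIGraph) else g


def _graph_id(g: Union[PLIGraph, nx.MultiGraph], i: int) -> str:
    if isinstance(g, PLIGraph):
        return g.graph_id
    return str(g.graph.get("graph_id", f"graph_{i}"))


def _prepare(graphs: Sequence[Union[PLIGraph, nx.MultiGraph]]) -> list[_MinedGraph]:
    return [_MinedGraph(_graph_id(g, i), _as_multigraph(g)) for i, g in enumerate(graphs)]


# ==========================================================================
# DFS codes
# ==========================================================================

# A DFS-code edge: (frm, to, label_frm, edge_label, label_to); forward
# edges introduce node `to` = max+1, backward edges have to < frm.
CodeEdge = tuple[int, int, str, str, str]


def _ext_order_key(t: CodeEdge):
    """gSpan's total order on extensions of one code.

    Backward edges precede forward ones; backward: smaller target first;
    forward: larger source first; then label lexicographic.
    """
    frm, to, lfrm, el, lto = t
    if to < frm:  # backward
        return (0, to, el, "", "")
    return (1, -frm, lfrm, el, lto)


class _PDFS:
    """One projected occurrence of a code edge: links form the embedding."""

    __slots__ = ("gidx", "u", "v", "eid", "prev")

    def __init__(self, gidx: int, u: int, v: int, eid: int, prev: Optional["_PDFS"]):
        self.gidx = gidx
        self.u = u  # image of the code edge's `frm`
        self.v = v  # image of `to`
        self.eid = eid
        self.prev = prev


def _history(code: list[CodeEdge], p: _PDFS) -> tuple[dict[int, int], set[int]]:
    """Pattern-node -> graph-node image and the set of used edge ids."""
    chain: list[_PDFS] = []
    while p is not None:
        chain.append(p)
        p = p.prev
    chain.reverse()
    image: dict[int, int] = {}
    used: set[int] = set()
    for t, step in zip(code, chain):
        frm, to = t[0], t[1]
        image[frm] = step.u
        image[to] = step.v
        used.add(step.eid)
    return image, used


def _rightmost_path(code: list[CodeEdge]) -> list[int]:
    """Pattern nodes from the root to the rightmost vertex."""
    rightmost = max(t[1] for t in code) if any(t[1] > t[0] for t in code) else 1
    path = [rightmost]
    cur = rightmost
    for frm, to, *_ in reversed(code):
        if to == cur and to > frm:
            path.append(frm)
            cur = frm
    path.reverse()
    return path


def _node_labels_of_code(code: list[CodeEdge]) -> dict[int, str]:
    labels: dict[int, str] = {}
    for frm, to, lfrm, _el, lto in code:
        labels.setdefault(frm, lfrm)
        labels.setdefault(to, lto)
    return labels


def _gather_extensions(code: list[CodeEdge], projections: list[_PDFS],
                       dataset: list[_MinedGraph]) -> dict[CodeEdge, list[_PDFS]]:
    """Rightmost extensions of a code over all its occurrences.

    Generates backward edges from the rightmost vertex to rightmost-path
    vertices (including parallel edges through unused edge ids) and
    forward edges from every rightmost-path vertex; non-canonical
    candidates are rejected later by the minimality test.
    """
    rmpath = _rightmost_path(code)
    vr = rmpath[-1]
    labels = _node_labels_of_code(code)
    exts: dict[CodeEdge, list[_PDFS]] = {}
    for p in projections:
        g = dataset[p.gidx]
        image, used = _history(code, p)
        rm_images = {image[vi]: vi for vi in rmpath}
        ur = image[vr]
        # Backward extensions from the rightmost vertex.
        for eid, nbr, el in g.adj[ur]:
            if eid in used:
                continue
            vi = rm_images.get(nbr)
            if vi is None or vi == vr:
                continue
            t: CodeEdge = (vr, vi, labels[vr], el, labels[vi])
            exts.setdefault(t, []).append(_PDFS(p.gidx, ur, nbr, eid, p))
        # Forward extensions from rightmost-path vertices.
        mapped = set(image.values())
        for vi in rmpath:
            ui = image[vi]
            for eid, nbr, el in g.adj[ui]:
                if eid in used or nbr in mapped:
                    continue
                t = (vi, vr + 1, labels[vi], el, g.labels[nbr])
                exts.setdefault(t, []).append(_PDFS(p.gidx, ui, nbr, eid, p))
    return exts


def _support(projections: list[_PDFS]) -> int:
    return len({p.gidx for p in projections})


def _code_to_graph(code: list[CodeEdge]) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for frm, to, lfrm, el, lto in code:
        if frm not in g:
            g.add_node(frm, label=lfrm)
        if to not in g:
            g.add_node(to, label=lto)
        g.add_edge(frm, to, label=el)
    return g


def _is_min(code: list[CodeEdge]) -> bool:
    """True iff `code` is the minimal DFS code of its own pattern graph."""
    pattern = _MinedGraph("_pattern", _code_to_graph(code))
    dataset = [pattern]
    # Minimal first edge over both orientations of every pattern edge.
    first: dict[CodeEdge, list[_PDFS]] = {}
    for eid, (u, v, el) in enumerate(pattern.edges):
        for a, b in ((u, v), (v, u)):
            la, lb = pattern.labels[a], pattern.labels[b]
            if la <= lb:
                t: CodeEdge = (0, 1, la, el, lb)
                first.setdefault(t, []).append(_PDFS(0, a, b, eid, None))
    min_first = min(first, key=lambda t: (t[2], t[3], t[4]))
    if min_first != code[0]:
        return False
    mincode = [min_first]
    projections = first[min_first]
    for i in range(1, len(code)):
        exts = _gather_extensions(mincode, projections, dataset)
        if not exts:
            return False
        t = min(exts, key=_ext_order_key)
        if t != code[i]:
            return False
        mincode.append(t)
        projections = exts[t]
    return True


# ==========================================================================
# Motifs
# ==========================================================================

@dataclass
class MotifGraph:
    """A frequent connected labeled subgraph with its mining provenance."""

    graph: nx.MultiGraph  # nodes 0..n-1 with 'label'; edges with 'label'
    support_count: int
    support_fraction: float  # the mining threshold this motif met
    graph_ids: list[str]
    cluster_id: Optional[int] = None
    motif_id: Optional[str] = None

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_labels(self) -> dict[int, str]:
        return {n: d["label"] for n, d in self.graph.nodes(data=True)}

    def edge_labels(self) -> list[tuple[int, int, str]]:
        return sorted((min(u, v), max(u, v), d["label"])
                      for u, v, d in self.graph.edges(data=True))


@dataclass
class MotifEmbedding:
    """One placement of a motif inside an input graph."""

    motif_id: Optional[str]
    graph_id: str
    node_map: dict[int, str]  # motif node -> graph node id
    edge_map: dict[tuple[int, int, int], tuple[str, str, int]]
    node_roles: dict[int, str] = field(default_factory=dict)
    node_atom_names: dict[int, str] = field(default_factory=dict)


@dataclass
class LigandAtomStat:
    motif_id: Optional[str]
    ligand_atom_name: str
    interaction_count: int
    graph_count: int


def mine_frequent_subgraphs(graphs: Sequence[Union[PLIGraph, nx.MultiGraph]],
                            min_support_fraction: float,
                            max_edges: Optional[int] = None,
                            cluster_id: Optional[int] = None) -> list[MotifGraph]:
    """All frequent connected subgraphs (>= 1 edge), one per isomorphism class.

    A subgraph is frequent when it occurs in at least
    ``ceil(min_support_fraction * len(graphs))`` distinct input graphs.
    ``max_edges`` optionally truncates pattern growth.
    """
    if not graphs:
        raise ValueError("empty graph dataset")
    if not (0 < min_support_fraction <= 1):
        raise ValueError(f"min_support_fraction must be in (0, 1], got {min_support_fraction}")
    dataset = _prepare(graphs)
    n = len(dataset)
    minsup = math.ceil(min_support_fraction * n - 1e-9)
    results: list[MotifGraph] = []

    def report(code: list[CodeEdge], projections: list[_PDFS]) -> None:
        gids = sorted({dataset[p.gidx].gid for p in projections})
        results.append(MotifGraph(
            graph=_code_to_graph(code),
            support_count=len(gids),
            support_fraction=min_support_fraction,
            graph_ids=gids,
            cluster_id=cluster_id,
        ))

    def grow(code: list[CodeEdge], projections: list[_PDFS]) -> None:
        if not _is_min(code):
            return
        report(code, projections)
        if max_edges is not None and len(code) >= max_edges:
            return
        exts = _gather_extensions(code, projections, dataset)
        for t in sorted(exts, key=_ext_order_key):
            if _support(exts[t]) >= minsup:
                grow(code + [t], exts[t])

    # Seed: all frequent single-edge codes (both orientations kept when the
    # endpoint labels coincide, so later extensions see every occurrence).
    first: dict[CodeEdge, list[_PDFS]] = {}
    for gidx, g in enumerate(dataset):
        for eid, (u, v, el) in enumerate(g.edges):
            for a, b in ((u, v), (v, u)):
                la, lb = g.labels[a], g.labels[b]
                if la <= lb:
                    t: CodeEdge = (0, 1, la, el, lb)
                    first.setdefault(t, []).append(_PDFS(gidx, a, b, eid, None))
    for t in sorted(first, key=lambda t: (t[2], t[3], t[4])):
        if _support(first[t]) >= minsup:
            grow([t], first[t])
    return results


def support_sweep(graphs: Sequence[Union[PLIGraph, nx.MultiGraph]],
                  fractions: Optional[Iterable[float]] = None,
                  max_edges: Optional[int] = None,
                  cluster_id: Optional[int] = None) -> dict[float, list[MotifGraph]]:
    """Mine once per support fraction (default 0.1..1.0 in steps of 0.1)."""
    if fractions is None:
        fractions = DEFAULT_SUPPORT_FRACTIONS
    out: dict[float, list[MotifGraph]] = {}
    for f in fractions:
        out[f] = mine_frequent_subgraphs(graphs, f, max_edges=max_edges,
                                         cluster_id=cluster_id)
    return out


# ==========================================================================
# Containment, maximality, mapping
# ==========================================================================

_NODE_MATCH = iso.categorical_node_match("label", None)


def _edge_subset_match(d_host: dict, d_pattern: dict) -> bool:
    """Pattern parallel-edge labels must be a sub-multiset of the host's."""
    host = Counter(a["label"] for a in d_host.values())
    pat = Counter(a["label"] for a in d_pattern.values())
    return all(host[k] >= v for k, v in pat.items())


def motif_contained_in(small: MotifGraph, big: MotifGraph) -> bool:
    """Label-preserving subgraph monomorphism test (VF2)."""
    if small.size > big.size or small.n_edges > big.n_edges:
        return False
    gm = iso.MultiGraphMatcher(big.graph, small.graph, node_match=_NODE_MATCH,
                               edge_match=_edge_subset_match)
    return gm.subgraph_is_monomorphic()


def motifs_isomorphic(a: MotifGraph, b: MotifGraph) -> bool:
    if a.size != b.size or a.n_edges != b.n_edges:
        return False
    gm = iso.MultiGraphMatcher(a.graph, b.graph, node_match=_NODE_MATCH,
                               edge_match=iso.categorical_multiedge_match("label", None))
    return gm.is_isomorphic()


def filter_maximal(motifs: Sequence[MotifGraph]) -> list[MotifGraph]:
    """Motifs not contained in any other motif of the same run."""
    kept = []
    for i, m in enumerate(motifs):
        contained = any(
            i != j and motif_contained_in(m, other)
            for j, other in enumerate(motifs)
        )
        if not contained:
            kept.append(m)
    return kept


def map_embeddings(motif: MotifGraph,
                   graph: Union[PLIGraph, nx.MultiGraph],
                   graph_id: Optional[str] = None) -> list[MotifEmbedding]:
    """All placements of a motif in one graph, one per node-image set.

    Automorphic re-labelings of the same placement are collapsed; the
    edge map picks, per motif edge, a distinct same-labeled graph edge
    between the image nodes.
    """
    host = _as_multigraph(graph)
    gid = graph_id or _graph_id(graph, 0)
    gm = iso.MultiGraphMatcher(host, motif.graph, node_match=_NODE_MATCH,
                               edge_match=_edge_subset_match)
    seen_images: set[frozenset] = set()
    out: list[MotifEmbedding] = []
    for mapping in gm.subgraph_monomorphisms_iter():
        inv = {pat: hostn for hostn, pat in mapping.items()}
        image = frozenset(inv.values())
        if image in seen_images:
            continue
        seen_images.add(image)
        edge_map: dict[tuple[int, int, int], tuple[str, str, int]] = {}
        taken: set[tuple[str, str, int]] = set()
        ok = True
        for u, v, k, d in motif.graph.edges(keys=True, data=True):
            hu, hv = inv[u], inv[v]
            candidates = [
                (hu, hv, hk) for hk, hd in host[hu][hv].items()
                if hd["label"] == d["label"] and (hu, hv, hk) not in taken
                and (hv, hu, hk) not in taken
            ]
            if not candidates:
                ok = False
                break
            choice = min(candidates, key=lambda c: str(c[2]))
            edge_map[(u, v, k)] = choice
            taken.add(choice)
        if not ok:
            continue
        out.append(MotifEmbedding(
            motif_id=motif.motif_id,
            graph_id=gid,
            node_map=dict(sorted(inv.items())),
            edge_map=edge_map,
            node_roles={p: host.nodes[n].get("role", "") for p, n in inv.items()},
            node_atom_names={p: host.nodes[n].get("atom_name", "") for p, n in inv.items()},
        ))
        if len(out) >= MAX_EMBEDDINGS_PER_GRAPH:
            logger.warning("embedding enumeration truncated at %d for motif %s in %s",
                           MAX_EMBEDDINGS_PER_GRAPH, motif.motif_id, gid)
            break
    return out


def map_embeddings_dataset(motif: MotifGraph,
                           graphs: Sequence[Union[PLIGraph, nx.MultiGraph]]
                           ) -> list[MotifEmbedding]:
    out = []
    for i, g in enumerate(graphs):
        out.extend(map_embeddings(motif, g, graph_id=_graph_id(g, i)))
    return out


def ligand_atom_stats(motif: MotifGraph,
                      embeddings: Sequence[MotifEmbedding]) -> list[LigandAtomStat]:
    """Per-ligand-atom contact statistics over a motif's embeddings.

    ``interaction_count`` counts (embedding, motif edge) incidences on the
    atom name; ``graph_count`` counts distinct input graphs contributing at
    least one incidence.
    """
    interactions: Counter = Counter()
    graphs_per_atom: dict[str, set[str]] = {}
    for emb in embeddings:
        for (u, v, _k) in emb.edge_map:
            for endpoint in (u, v):
                if emb.node_roles.get(endpoint) == "ligand":
                    name = emb.node_atom_names.get(endpoint, "")
                    interactions[name] += 1
                    graphs_per_atom.setdefault(name, set()).add(emb.graph_id)
    stats = [
        LigandAtomStat(motif_id=motif.motif_id, ligand_atom_name=name,
                       interaction_count=count,
                       graph_count=len(graphs_per_atom[name]))
        for name, count in interactions.items()
    ]
    stats.sort(key=lambda s: (-s.interaction_count, s.ligand_atom_name))
    return stats
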