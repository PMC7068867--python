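"""Binary path features over interaction graphs.

Each graph is summarised by the set of (property, path length, property)
triples it realises: the feature ``HP-4-HP`` is present when some simple
(node-repetition-free) path of four edges joins two hydrophobic atoms.
All simple paths up to a configurable length cap are enumerated; a node
carrying several types contributes each type independently at either
endpoint, and the two endpoint properties are canonicalised
lexicographically so the feature never encodes direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import networkx as nx
import pandas as pd

from plimotif.atom_typing import CODE_TYPES, TYPE_CODES
from plimotif.interaction_graph import PLIGraph

#: Default cap on path length (in edges); simple-path enumeration is
#: exponential in pathological graphs, the cap bounds the work.
DEFAULT_MAX_PATH_LENGTH = 10

FeatureKey = tuple[str, int, str]  # (prop_code_a, length, prop_code_b), a <= b


def feature_name(key: FeatureKey) -> str:
    a, n, b = key
    return f"{a}-{n}-{b}"


def parse_feature_name(name: str) -> FeatureKey:
    a, n, b = name.split("-")
    if a not in CODE_TYPES or b not in CODE_TYPES:
        raise ValueError(f"unknown property code in feature {name!r}")
    return (a, int(n), b)


def _canonical(a: str, n: int, b: str) -> FeatureKey:
    return (a, n, b) if a <= b else (b, n, a)


def _as_nx(graph: Union[PLIGraph, nx.Graph]) -> nx.Graph:
    return graph.graph if isinstance(graph, PLIGraph) else graph


def _node_codes(g: nx.Graph, node) -> list[str]:
    types = g.nodes[node].get("types", "")
    return [TYPE_CODES[t] for t in types.split(",") if t]


def enumerate_path_features(graph: Union[PLIGraph, nx.Graph],
                            max_length: int = DEFAULT_MAX_PATH_LENGTH) -> set[FeatureKey]:
    """All (property, length, property) features realised by simple paths.

    Parallel edges do not multiply paths: a path is a node sequence.  Nodes
    with an empty type set can appear inside a path but contribute no
    endpoint property.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    g = _as_nx(graph)
    simple = nx.Graph(g)  # collapse parallel edges; paths are node sequences
    nodes = sorted(simple.nodes)
    codes = {n: _node_codes(simple, n) for n in nodes}
    features: set[FeatureKey] = set()

    def dfs(start, current, visited: set, length: int) -> None:
        for nbr in simple.neighbors(current):
            if nbr in visited:
                continue
            # Record endpoint pair once per unordered node pair: only when
            # the far endpoint sorts after the start node.
            if nbr > start:
                for p in codes[start]:
                    for q in codes[nbr]:
                        features.add(_canonical(p, length + 1, q))
            if length + 1 < max_length:
                visited.add(nbr)
                dfs(start, nbr, visited, length + 1)
                visited.remove(nbr)

    for start in nodes:
        dfs(start, start, {start}, 0)
    return features


@dataclass
class FeatureMatrix:
    """Binary graph x feature matrix with canonical column order."""

    data: pd.DataFrame  # index: graph_ids; columns: feature names; values 0/1
    max_length: int

    @property
    def graph_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="graph_id")

    @classmethod
    def from_csv(cls, path, max_length: int = DEFAULT_MAX_PATH_LENGTH) -> "FeatureMatrix":
        return cls(data=pd.read_csv(path, index_col="graph_id"), max_length=max_length)


def assemble_matrix(graphs: Iterable[Union[PLIGraph, nx.Graph]],
                    max_length: int = DEFAULT_MAX_PATH_LENGTH) -> FeatureMatrix:
    """Feature matrix over a dataset: rows in input order, columns the
    union of observed features sorted by (property, length, property)."""
    graphs = list(graphs)
    if len(graphs) < 2:
        raise ValueError(f"need at least 2 graphs to assemble a matrix, got {len(graphs)}")
    ids = []
    feature_sets = []
    for i, g in enumerate(graphs):
        gid = g.graph_id if isinstance(g, PLIGraph) else _as_nx(g).graph.get("graph_id", f"graph_{i}")
        ids.append(gid)
        feature_sets.append(enumerate_path_features(g, max_length))
    all_keys = sorted(set().union(*feature_sets))
    columns = [feature_name(k) for k in all_keys]
    rows = [[1 if k in fs else 0 for k in all_keys] for fs in feature_sets]
    df = pd.DataFrame(rows, index=ids, columns=columns, dtype=int)
    return FeatureMatrix(data=df, max_length=max_length)
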