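"""Drug-interaction networks: edge-list I/O, descriptive statistics, overlaps.

A drug-drug interaction (DDI) network is an undirected simple graph whose
nodes are drug identifiers (opaque, case-sensitive strings) and whose edges
are interacting pairs.  Interaction direction, if present in the source, is
ignored; reciprocal duplicates collapse to a single edge and self-loops are
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DrugNetwork",
    "NetworkStats",
    "OverlapReport",
    "load_edge_list",
    "save_edge_list",
    "network_stats",
    "network_overlap",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file is malformed."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class DrugNetwork:
    """Undirected simple graph over drug identifiers.

    Parameters
    ----------
    name : str
        Label for the network (used in reports).
    graph : networkx.Graph
        Underlying simple graph.  Self-loops are removed on construction.
    """

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], name: str = "",
                   nodes: Iterable[str] | None = None) -> "DrugNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(name=name, graph=g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        """Canonicalized (lexicographically ordered) undirected edge set."""
        return {_canonical(u, v) for u, v in self.graph.edges}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of one network.

    ``diameter`` and ``avg_path_length`` are hop counts on the giant
    component (NaN for an edgeless network); ``avg_degree`` is 2|E|/|V|;
    ``clustering_coeff`` is the mean local clustering coefficient with
    degree<2 nodes contributing 0; ``giant_component_fraction`` is the share
    of nodes in the largest connected component.
    """

    name: str
    n_nodes: int
    n_edges: int
    avg_degree: float
    diameter: float
    avg_path_length: float
    clustering_coeff: float
    giant_component_fraction: float

    def to_row(self) -> dict:
        return {
            "network": self.name,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "diameter": self.diameter,
            "avg_path_length": self.avg_path_length,
            "clustering": self.clustering_coeff,
            "giant_component": self.giant_component_fraction,
        }


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise shared-edge counts and overlap proportions between networks.

    ``proportions[i, j]`` is shared(i, j) / min(|E_i|, |E_j|); NaN when a
    member of the pair has no edges.
    """

    names: tuple[str, ...]
    edge_counts: tuple[int, ...]
    shared: np.ndarray
    proportions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Compact table: diagonal = edge counts, lower = shared counts,
        upper = proportions (mirrors the usual data-source overlap layout)."""
        k = len(self.names)
        out = np.zeros((k, k))
        for i in range(k):
            out[i, i] = self.edge_counts[i]
            for j in range(k):
                if i > j:
                    out[i, j] = self.shared[i, j]
                elif i < j:
                    out[i, j] = self.proportions[i, j]
        return pd.DataFrame(out, index=self.names, columns=self.names)


def load_edge_list(path: str | Path, name: str | None = None) -> DrugNetwork:
    """Read a two-column whitespace/tab-separated edge list.

    Lines starting with ``#`` are comments.  Reciprocal duplicates and
    self-loops are silently collapsed/dropped (counts retrievable from the
    returned graph vs. the raw line count).  Raises on malformed lines
    (fewer than two tokens) naming the line number, and on files containing
    no edges at all.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two drug identifiers, got {stripped!r}"
                )
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise EdgeListParseError(f"{path}: no edges found (empty network)")
    return DrugNetwork.from_edges(edges, name=name if name is not None else path.stem)


def save_edge_list(net: DrugNetwork, path: str | Path) -> None:
    """Write the canonicalized edge list: within-pair lexicographic order,
    lines sorted, tab-separated."""
    lines = sorted(net.edge_set())
    with Path(path).open("w") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def network_stats(net: DrugNetwork) -> NetworkStats:
    """Compute the descriptive statistics block for one network.

    Diameter and average path length are taken on the giant component with
    unweighted breadth-first shortest paths; the average is over connected
    ordered pairs.  For an edgeless graph both are NaN, clustering is 0 and
    the giant component fraction is 1/|V|.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network_stats requires at least one node")
    m = g.number_of_edges()
    avg_degree = 2.0 * m / n
    if m == 0:
        return NetworkStats(net.name, n, 0, 0.0, math.nan, math.nan, 0.0, 1.0 / n)
    components = list(nx.connected_components(g))
    giant = max(components, key=len)
    sub = g.subgraph(giant)
    if len(giant) > 1:
        diameter = float(nx.diameter(sub))
        avg_path = float(nx.average_shortest_path_length(sub))
    else:  # pragma: no cover - unreachable when m > 0
        diameter = math.nan
        avg_path = math.nan
    clustering = float(nx.average_clustering(g, count_zeros=True))
    return NetworkStats(
        name=net.name,
        n_nodes=n,
        n_edges=m,
        avg_degree=avg_degree,
        diameter=diameter,
        avg_path_length=avg_path,
        clustering_coeff=clustering,
        giant_component_fraction=len(giant) / n,
    )


def network_overlap(nets: list[DrugNetwork]) -> OverlapReport:
    """Pairwise undirected-edge overlaps between two or more networks.

    The overlap proportion of a pair is the number of shared edges divided
    by the smaller of the two edge counts.
    """
    if len(nets) < 2:
        raise ValueError("network_overlap requires at least two networks")
    edge_sets = [net.edge_set() for net in nets]
    k = len(nets)
    shared = np.zeros((k, k), dtype=int)
    prop = np.full((k, k), np.nan)
    for i in range(k):
        shared[i, i] = len(edge_sets[i])
        prop[i, i] = 1.0 if edge_sets[i] else np.nan
        for j in range(i + 1, k):
            s = len(edge_sets[i] & edge_sets[j])
            shared[i, j] = shared[j, i] = s
            denom = min(len(edge_sets[i]), len(edge_sets[j]))
            if denom > 0:
                prop[i, j] = prop[j, i] = s / denom
    return OverlapReport(
        names=tuple(net.name for net in nets),
        edge_counts=tuple(len(es) for es in edge_sets),
        shared=shared,
        proportions=prop,
    )


def stats_table(stats: list[NetworkStats]) -> pd.DataFrame:
    """Stack per-network statistics into one report table."""
    return pd.DataFrame([s.to_row() for s in stats])
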