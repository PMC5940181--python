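"""Topological pair-similarity indices for link prediction.

Eight local indices over a pair (x, y) with common-neighbor set
Lambda = Gamma(x) & Gamma(y):

* ``cn``   common neighbors, |Lambda|
* ``jc``   Jaccard coefficient, |Lambda| / |Gamma(x) | Gamma(y)|
* ``aai``  Adamic/Adar, sum over z in Lambda of 1/ln d(z)
* ``pa``   preferential attachment, d(x) * d(y)
* ``rai``  resource allocation, sum over z in Lambda of 1/d(z)
* ``ccn``  community common neighbors: cn plus one point per community
           shared by x, y and the common neighbor
* ``cra``  community resource allocation: (1 + shared communities)/d(i)
           summed over common neighbors
* ``wic``  within/inter-cluster ratio |Lambda_W| / (|Lambda_IC| + delta)
           under a non-overlapping partition

CCN and CRA use the overlapping community view C(n) (a set of community
ids per node); WIC requires the partition view (exactly one community per
node).  All eight are symmetric in (x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import DrugNetwork

__all__ = [
    "CommunityAssignment",
    "NeighborhoodIndex",
    "detect_communities",
    "classical_index",
    "community_index",
    "pair_features",
    "featurize_pairs",
    "TopologicalPairFeaturizer",
    "TOPO_FEATURES",
]

TOPO_FEATURES = ("cn", "jc", "aai", "pa", "rai", "ccn", "cra", "wic")
CLASSICAL_KINDS = ("cn", "jc", "aai", "pa", "rai")
COMMUNITY_KINDS = ("ccn", "cra", "wic")

#: default WIC denominator offset; small so a pair with no inter-cluster
#: common neighbors gets a large but finite score
DEFAULT_DELTA = 0.001


@dataclass
class NeighborhoodIndex:
    """Adjacency as explicit neighbor sets, for set-arithmetic indices."""

    neighbors: dict[str, frozenset]

    @classmethod
    def from_network(cls, net: DrugNetwork) -> "NeighborhoodIndex":
        g = net.graph
        return cls({n: frozenset(g.neighbors(n)) for n in g.nodes})

    def degree(self, node: str) -> int:
        return len(self.neighbors[node])

    def __contains__(self, node: str) -> bool:
        return node in self.neighbors


@dataclass
class CommunityAssignment:
    """Node -> community membership in two views.

    ``overlapping``: node -> set of community ids (>= 1 each); feeds the
    CCN/CRA formulas.  ``partition``: node -> single community id; feeds
    WIC.  For a non-overlapping method the overlapping view is the
    singleton of the partition id.
    """

    overlapping: dict[str, frozenset]
    partition: dict[str, int]
    method: str = "partition-modularity"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.partition) ^ set(self.overlapping)
        if missing:
            raise ValueError(f"views cover different nodes: {sorted(missing)[:5]}")

    def communities(self, node: str) -> frozenset:
        return self.overlapping[node]

    def n_communities(self) -> int:
        return len(set(self.partition.values()))


def detect_communities(net: DrugNetwork,
                       method: str = "partition-modularity",
                       seed: int = 0, k_clique: int = 3) -> CommunityAssignment:
    """Assign every node to communities.

    ``partition-modularity`` runs greedy modularity maximization (each node
    in exactly one community; the overlapping view holds singleton sets).
    ``overlapping-clique`` runs k-clique percolation (k=3 by default); nodes
    outside any clique community become singletons, and the partition view
    picks each node's lowest community id.  Isolated nodes always form
    singleton communities.  Deterministic given seed and method.
    """
    g = net.graph
    if g.number_of_nodes() < 1:
        raise ValueError("community detection needs at least one node")
    if method == "partition-modularity":
        if g.number_of_edges() == 0:
            groups = [{n} for n in sorted(g.nodes)]
        else:
            groups = [set(c) for c in
                      nx.community.greedy_modularity_communities(g)]
        # sort for a stable community numbering independent of nx internals
        groups.sort(key=lambda c: sorted(c)[0])
        partition = {n: cid for cid, grp in enumerate(groups) for n in grp}
        overlapping = {n: frozenset([cid]) for n, cid in partition.items()}
    elif method == "overlapping-clique":
        overlapping_raw: dict[str, set[int]] = {n: set() for n in g.nodes}
        cliques = [set(c) for c in nx.community.k_clique_communities(g, k_clique)]
        cliques.sort(key=lambda c: sorted(c)[0])
        for cid, grp in enumerate(cliques):
            for n in grp:
                overlapping_raw[n].add(cid)
        next_id = len(cliques)
        for n in sorted(g.nodes):
            if not overlapping_raw[n]:
                overlapping_raw[n].add(next_id)
                next_id += 1
        overlapping = {n: frozenset(s) for n, s in overlapping_raw.items()}
        partition = {n: min(s) for n, s in overlapping.items()}
    else:
        raise ValueError(f"unknown community method {method!r}")
    return CommunityAssignment(overlapping=overlapping, partition=partition,
                               method=method,
                               params={"seed": seed, "k_clique": k_clique})


def _check_pair(x: str, y: str, idx: NeighborhoodIndex) -> None:
    if x == y:
        raise ValueError(f"pair endpoints must differ, got ({x!r}, {y!r})")
    for node in (x, y):
        if node not in idx:
            raise KeyError(f"node {node!r} not in the network")


def classical_index(kind: str, x: str, y: str, idx: NeighborhoodIndex) -> float:
    """One of the five community-agnostic indices (cn, jc, aai, pa, rai)."""
    _check_pair(x, y, idx)
    gx, gy = idx.neighbors[x], idx.neighbors[y]
    common = gx & gy
    if kind == "cn":
        return float(len(common))
    if kind == "jc":
        union = gx | gy
        return len(common) / len(union) if union else 0.0
    if kind == "aai":
        # every common neighbor in a simple graph has degree >= 2, so ln is safe
        return sum(1.0 / math.log(idx.degree(z)) for z in common)
    if kind == "pa":
        return float(len(gx) * len(gy))
    if kind == "rai":
        return sum(1.0 / idx.degree(z) for z in common)
    raise ValueError(f"unknown classical index {kind!r}")


def community_index(kind: str, x: str, y: str, idx: NeighborhoodIndex,
                    comm: CommunityAssignment,
                    delta: float = DEFAULT_DELTA) -> float:
    """One of the three community-aware indices (ccn, cra, wic)."""
    _check_pair(x, y, idx)
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    common = idx.neighbors[x] & idx.neighbors[y]
    if kind == "ccn":
        cx, cy = comm.communities(x), comm.communities(y)
        return float(len(common)) + sum(
            len(comm.communities(i) & cx & cy) for i in common)
    if kind == "cra":
        cx, cy = comm.communities(x), comm.communities(y)
        return sum((1 + len(comm.communities(i) & cx & cy)) / idx.degree(i)
                   for i in common)
    if kind == "wic":
        px, py = comm.partition[x], comm.partition[y]
        if px == py:
            within = sum(1 for i in common if comm.partition[i] == px)
        else:
            within = 0
        inter = len(common) - within
        return within / (inter + delta)
    raise ValueError(f"unknown community index {kind!r}")


def pair_features(x: str, y: str, idx: NeighborhoodIndex,
                  comm: CommunityAssignment,
                  delta: float = DEFAULT_DELTA) -> dict[str, float]:
    """All eight indices for one pair, keyed by feature name."""
    out = {kind: classical_index(kind, x, y, idx) for kind in CLASSICAL_KINDS}
    for kind in COMMUNITY_KINDS:
        out[kind] = community_index(kind, x, y, idx, comm, delta)
    return out


class TopologicalPairFeaturizer:
    """Transformer appending the eight topological feature columns to a
    labeled pair table.

    Parameters
    ----------
    community_method : str
        ``"partition-modularity"`` or ``"overlapping-clique"``.
    delta : float
        WIC denominator offset.
    seed : int
        Community-detection seed (recorded; the default method is
        deterministic regardless).

    The graph the features are computed on is whatever network ``fit``
    receives — the full network in the classical workflow, or the training
    graph when evaluation must not see held-out edges.
    """

    def __init__(self, community_method: str = "partition-modularity",
                 delta: float = DEFAULT_DELTA, seed: int = 0):
        self.community_method = community_method
        self.delta = delta
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"community_method": self.community_method,
                "delta": self.delta, "seed": self.seed}

    def set_params(self, **params) -> "TopologicalPairFeaturizer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, net: DrugNetwork,
            communities: CommunityAssignment | None = None) -> "TopologicalPairFeaturizer":
        """Index the graph and detect (or adopt) its communities."""
        self.index_ = NeighborhoodIndex.from_network(net)
        if communities is None:
            communities = detect_communities(net, self.community_method,
                                             seed=self.seed)
        self.communities_ = communities
        return self

    def transform(self, pairs: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of ``pairs`` with columns cn..wic appended.

        Raises if any pair endpoint is absent from the fitted network (a
        silent zero would poison the downstream learner).
        """
        if not hasattr(self, "index_"):
            raise RuntimeError("featurizer is not fitted; call fit(network) first")
        bad = [
            (u, v) for u, v in zip(pairs["drug_id_1"], pairs["drug_id_2"])
            if u not in self.index_ or v not in self.index_
        ]
        if bad:
            raise KeyError(
                f"{len(bad)} pairs have endpoints outside the network, "
                f"e.g. {bad[:3]}")
        rows = [
            pair_features(u, v, self.index_, self.communities_, self.delta)
            for u, v in zip(pairs["drug_id_1"], pairs["drug_id_2"])
        ]
        feats = pd.DataFrame(rows, columns=list(TOPO_FEATURES), index=pairs.index)
        out = pd.concat([pairs.reset_index(drop=True),
                         feats.reset_index(drop=True)], axis=1)
        out.attrs.update(pairs.attrs)
        return out

    def fit_transform(self, net: DrugNetwork, pairs: pd.DataFrame) -> pd.DataFrame:
        return self.fit(net).transform(pairs)


def featurize_pairs(pairs: pd.DataFrame, net: DrugNetwork,
                    comm: CommunityAssignment | None = None,
                    delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Functional wrapper over :class:`TopologicalPairFeaturizer`."""
    feat = TopologicalPairFeaturizer(delta=delta)
    feat.fit(net, communities=comm)
    return feat.transform(pairs)
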