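"""Pair enumeration, train/test splitting and balanced negative sampling.

The universal pair space U of a network with node set V contains
|V|(|V|-1)/2 unordered pairs; observed interactions E are the positives and
candidate negatives live in U - E.  Two splitting modes are supported:

* an *edge split* partitioning E into training/test edge sets (used by the
  leakage-safe pipeline mode, where test edges are hidden from the graph
  before topological featurization), and
* an *example split* stratifying an already-balanced labeled pair set
  66/33 (the classical resampling workflow).

Labeled pair sets are pandas DataFrames with columns
``drug_id_1, drug_id_2, label`` (plus appended feature columns later);
provenance (seed, sampling mode) travels in ``DataFrame.attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DrugNetwork, _canonical

__all__ = [
    "EdgeSplit",
    "universal_pair_count",
    "split_edges",
    "build_balanced_pairs",
    "partition_examples",
    "save_pairs",
    "load_pairs",
]

PAIR_COLUMNS = ["drug_id_1", "drug_id_2", "label"]

# rejection sampling gives up after this many multiples of the request and
# falls back to explicit enumeration of U - E
_REJECTION_CAP = 50


def universal_pair_count(net: DrugNetwork) -> int:
    """|U| = |V|(|V|-1)/2, the number of unordered node pairs."""
    n = net.n_nodes
    if n < 2:
        raise ValueError(f"need at least 2 nodes for a pair space, got {n}")
    return n * (n - 1) // 2


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint partition of a network's edge set into train and test."""

    train_edges: frozenset
    test_edges: frozenset
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        assert not (self.train_edges & self.test_edges)


def split_edges(net: DrugNetwork, train_frac: float = 0.66,
                seed: int = 0) -> EdgeSplit:
    """Uniform random partition of E into train/test edge sets.

    The training count is floor(train_frac * |E|); the remainder goes to
    test.  Deterministic given the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    edges = sorted(net.edge_set())
    m = len(edges)
    n_train = int(np.floor(train_frac * m))
    if n_train < 1 or m - n_train < 1:
        raise ValueError(
            f"cannot split {m} edges into non-empty partitions at fraction {train_frac}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    train = frozenset(edges[i] for i in order[:n_train])
    test = frozenset(edges[i] for i in order[n_train:])
    return EdgeSplit(train, test, train_frac, seed)


def _sample_negatives(net: DrugNetwork, n_neg: int, rng: np.random.Generator):
    """Uniform sample without replacement from U - E.

    Rejection-samples random pairs against the edge set; for dense or tiny
    graphs (cap exceeded) it enumerates U - E explicitly.
    """
    nodes = sorted(net.graph.nodes)
    n = len(nodes)
    n_universe = n * (n - 1) // 2
    n_available = n_universe - net.n_edges
    if n_neg > n_available:
        raise ValueError(
            f"requested {n_neg} negative pairs but only {n_available} "
            f"non-edges exist (deficit {n_neg - n_available})"
        )
    edge_set = net.edge_set()
    chosen: set[tuple[str, str]] = set()
    budget = _REJECTION_CAP * n_neg
    draws = 0
    while len(chosen) < n_neg and draws < budget:
        k = n_neg - len(chosen)
        ii = rng.integers(0, n, size=2 * k)
        for a, b in zip(ii[:k], ii[k:]):
            draws += 1
            if a == b:
                continue
            pair = _canonical(nodes[a], nodes[b])
            if pair in edge_set or pair in chosen:
                continue
            chosen.add(pair)
            if len(chosen) == n_neg:
                break
    if len(chosen) < n_neg:
        # exact path: enumerate all non-edges and subsample
        non_edges = [
            _canonical(nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if _canonical(nodes[i], nodes[j]) not in edge_set
        ]
        idx = rng.choice(len(non_edges), size=n_neg, replace=False)
        chosen = {non_edges[i] for i in idx}
    return sorted(chosen)


def build_balanced_pairs(net: DrugNetwork, positives=None, ratio: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Labeled pair set: given positives (default: all edges) plus negatives
    sampled uniformly from U - E at ``ratio`` negatives per positive.

    Negatives are drawn against the *full* edge set regardless of any
    train/test split, so no sampled negative is a known interaction.
    """
    if positives is None:
        positives = net.edge_set()
    else:
        positives = {_canonical(u, v) for u, v in positives}
        missing = positives - net.edge_set()
        if missing:
            raise ValueError(f"{len(missing)} positive pairs are not edges of the network")
    if not positives:
        raise ValueError("no positive pairs supplied")
    n_neg = int(round(ratio * len(positives)))
    rng = np.random.default_rng(seed)
    negatives = _sample_negatives(net, n_neg, rng)
    rows = [(u, v, 1) for u, v in sorted(positives)] + [(u, v, 0) for u, v in negatives]
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    df.attrs["seed"] = seed
    df.attrs["sampling"] = f"balanced-1:{ratio:g}"
    return df


def partition_examples(pairs: pd.DataFrame, train_frac: float = 0.66,
                       seed: int = 0, stratified: bool = True):
    """Split labeled examples into train/test subsets.

    Stratified mode preserves the class ratio within one example per class;
    per-class training counts use floor with ties resolved toward training.
    Returns ``(train, test)`` DataFrames whose union is the input and whose
    intersection is empty.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    if stratified:
        train_parts, test_parts = [], []
        for _, grp in pairs.groupby("label", sort=True):
            if len(grp) < 2:
                raise ValueError("stratified split needs >= 2 examples per class")
            order = rng.permutation(len(grp))
            n_train = int(np.floor(train_frac * len(grp)))
            n_train = min(max(n_train, 1), len(grp) - 1)
            train_parts.append(grp.iloc[order[:n_train]])
            test_parts.append(grp.iloc[order[n_train:]])
        train = pd.concat(train_parts).sort_index().reset_index(drop=True)
        test = pd.concat(test_parts).sort_index().reset_index(drop=True)
    else:
        order = rng.permutation(len(pairs))
        n_train = int(np.floor(train_frac * len(pairs)))
        if n_train < 1 or n_train >= len(pairs):
            raise ValueError("split leaves an empty subset")
        train = pairs.iloc[np.sort(order[:n_train])].reset_index(drop=True)
        test = pairs.iloc[np.sort(order[n_train:])].reset_index(drop=True)
    for df in (train, test):
        df.attrs.update(pairs.attrs)
        df.attrs["split_seed"] = seed
    return train, test


def save_pairs(pairs: pd.DataFrame, path) -> None:
    """Write a labeled pair set (with any feature columns) as headered TSV."""
    pairs.to_csv(path, sep="\t", index=False)


def load_pairs(path) -> pd.DataFrame:
    """Read a labeled pair TSV written by :func:`save_pairs`."""
    return pd.read_csv(path, sep="\t", dtype={"drug_id_1": str, "drug_id_2": str})
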