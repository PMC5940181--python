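"""Synthetic DDI-like datasets: community-structured networks with
correlated attribute channels and fingerprints.

The generator emulates the statistical regime of curated interaction
networks — heavy-tailed degrees, high clustering, a giant component
covering essentially all nodes — with a degree-corrected planted-partition
network model, and couples three attribute channels (therapeutic-,
indexing- and side-effect-like code sets) plus binary fingerprints to the
community structure through a single signal-strength knob ``signal``
(lambda): at 1 every drug draws its attributes from a community-specific
pool (disjoint across communities) and its fingerprint from a community
prototype; at 0 attributes are independent of the network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DrugNetwork, network_stats, save_edge_list, NetworkStats
from .semantics import AttributeCatalog, FingerprintCatalog

__all__ = ["SynthConfig", "SynthDataset", "generate", "summarize", "write_dataset"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``degree_exponent`` is the Pareto tail exponent of the node propensity
    distribution (heavier tail = more hubs); ``None`` switches degree
    correction off, giving a homogeneous planted partition.  ``signal``
    is the fraction of each drug's attribute/fingerprint content drawn
    from its community pool rather than the global pool.
    """

    n_drugs: int = 500
    n_communities: int = 5
    p_in: float = 0.3
    p_out: float = 0.01
    degree_exponent: float | None = 2.5
    vocab_sizes: dict = field(default_factory=lambda: {
        "atc": 70, "mesh": 150, "ade": 200})
    codes_per_drug: dict = field(default_factory=lambda: {
        "atc": 4, "mesh": 8, "ade": 10})
    n_bits: int = 1024
    bit_density: float = 0.1
    signal: float = 1.0
    missingness: dict = field(default_factory=lambda: {
        "atc": 0.0, "chem": 0.0, "mesh": 0.0, "ade": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError(f"signal must be in [0, 1], got {self.signal}")
        if min(self.n_drugs, self.n_communities, self.n_bits) < 1:
            raise ValueError("all counts must be positive")
        if self.n_communities > self.n_drugs:
            raise ValueError("more communities than drugs")


@dataclass
class SynthDataset:
    """One generated dataset plus its ground truth and config echo."""

    network: DrugNetwork
    atc: AttributeCatalog
    mesh: AttributeCatalog
    ade: AttributeCatalog
    fingerprints: FingerprintCatalog
    community_labels: dict[str, int]
    config: SynthConfig

    def catalogs(self) -> dict:
        return {"atc": self.atc, "mesh": self.mesh, "ade": self.ade,
                "chem": self.fingerprints}


def _propensities(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.degree_exponent is None:
        return np.ones(cfg.n_drugs)
    # Pareto(min=1) with tail exponent; normalized to unit mean so p_in/p_out
    # keep their interpretation as average block densities
    raw = rng.pareto(cfg.degree_exponent - 1.0, size=cfg.n_drugs) + 1.0
    return raw / raw.mean()


def _sample_edges(cfg: SynthConfig, labels: np.ndarray, theta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_drugs
    iu, ju = np.triu_indices(n, k=1)
    base = np.where(labels[iu] == labels[ju], cfg.p_in, cfg.p_out)
    prob = np.clip(base * theta[iu] * theta[ju], 0.0, 1.0)
    keep = rng.random(prob.size) < prob
    return np.column_stack([iu[keep], ju[keep]])


def generate(config: SynthConfig) -> SynthDataset:
    """Draw one dataset; fully deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_drugs
    drugs = [f"D{i:05d}" for i in range(n)]
    labels = np.arange(n) % cfg.n_communities
    block = n / cfg.n_communities
    expected_degree = (block - 1) * cfg.p_in + (n - block) * cfg.p_out
    if expected_degree < 1.0:
        warnings.warn(
            f"expected degree {expected_degree:.2f} < 1; the network will be "
            "mostly isolated nodes", stacklevel=2)
    theta = _propensities(cfg, rng)
    edge_idx = _sample_edges(cfg, labels, theta, rng)
    net = DrugNetwork.from_edges(
        ((drugs[i], drugs[j]) for i, j in edge_idx),
        name=f"synth-seed{cfg.seed}", nodes=drugs)

    # attribute channels: disjoint community pools inside a global vocabulary
    catalogs = {}
    for channel, vocab_size in cfg.vocab_sizes.items():
        vocab = [f"{channel.upper()}{t:04d}" for t in range(vocab_size)]
        pool_size = vocab_size // cfg.n_communities
        pools = [vocab[c * pool_size:(c + 1) * pool_size]
                 for c in range(cfg.n_communities)]
        per_drug = cfg.codes_per_drug[channel]
        miss_rate = cfg.missingness.get(channel, 0.0)
        codes: dict[str, frozenset] = {}
        for i, drug in enumerate(drugs):
            if rng.random() < miss_rate:
                continue
            pool = pools[labels[i]]
            chosen: set[str] = set()
            for _ in range(per_drug):
                if rng.random() < cfg.signal:
                    chosen.add(pool[rng.integers(len(pool))])
                else:
                    chosen.add(vocab[rng.integers(vocab_size)])
            codes[drug] = frozenset(chosen)
        catalogs[channel] = AttributeCatalog(channel=channel, codes=codes)

    # fingerprints: community prototypes blended with global noise
    prototypes = rng.random((cfg.n_communities, cfg.n_bits)) < cfg.bit_density
    miss_chem = cfg.missingness.get("chem", 0.0)
    fps: dict[str, np.ndarray] = {}
    for i, drug in enumerate(drugs):
        if rng.random() < miss_chem:
            continue
        noise = rng.random(cfg.n_bits) < cfg.bit_density
        take_proto = rng.random(cfg.n_bits) < cfg.signal
        fps[drug] = np.where(take_proto, prototypes[labels[i]], noise).astype(np.uint8)

    return SynthDataset(
        network=net,
        atc=catalogs["atc"],
        mesh=catalogs["mesh"],
        ade=catalogs["ade"],
        fingerprints=FingerprintCatalog(fingerprints=fps, n_bits=cfg.n_bits),
        community_labels={drugs[i]: int(labels[i]) for i in range(n)},
        config=cfg,
    )


def summarize(dataset: SynthDataset) -> tuple[NetworkStats, dict]:
    """Network statistics plus per-channel coverage (fraction of nodes with
    a record)."""
    stats = network_stats(dataset.network)
    n = dataset.network.n_nodes
    coverage = {
        "atc": dataset.atc.n_drugs / n,
        "mesh": dataset.mesh.n_drugs / n,
        "ade": dataset.ade.n_drugs / n,
        "chem": len(dataset.fingerprints.fingerprints) / n,
    }
    return stats, coverage


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the pipeline's input formats: edge TSV, three
    attribute TSVs, fingerprint TSV, and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "atc": outdir / "atc.tsv",
        "mesh": outdir / "mesh.tsv",
        "ade": outdir / "ade.tsv",
        "fingerprints": outdir / "fingerprints.tsv",
        "truth": outdir / "truth.json",
    }
    save_edge_list(dataset.network, paths["edges"])
    dataset.atc.to_tsv(paths["atc"])
    dataset.mesh.to_tsv(paths["mesh"])
    dataset.ade.to_tsv(paths["ade"])
    dataset.fingerprints.to_tsv(paths["fingerprints"])
    truth = {
        "community_labels": dataset.community_labels,
        "config": {k: v for k, v in asdict(dataset.config).items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
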