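"""End-to-end orchestration: featurize -> sample -> train -> evaluate -> compare.

Two featurization modes are supported and recorded in every report:

* ``paper`` — balanced labeled pairs are built over the full network,
  topological features are computed on the full graph, and the 66/33 split
  stratifies the labeled examples.  Positive test pairs' own edges are
  visible to the featurizer (the classical workflow; optimistic).
* ``leakage-safe`` — the edge set is split 66/33 first, test edges are
  removed from the graph before topological featurization, and train/test
  positives are the train/test edges.  Negatives are always sampled
  against the full edge set in both modes.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (FeatureDendrogram, GroupSimilarityComparison,
                         RankComparison, compare_classifiers, confusion_metrics,
                         curve_metrics, feature_dendrogram,
                         group_similarity_comparison)
from .models import (CLASSIFIER_FAMILIES, FEATURE_COLUMNS,
                     CombinedSimilarityClassifier, ImportanceReport,
                     TunedPairClassifier, feature_importance)
from .network import DrugNetwork, NetworkStats, load_edge_list, network_stats
from .sampling import build_balanced_pairs, partition_examples, split_edges
from .semantics import (AttributeCatalog, FingerprintCatalog,
                        SemanticPairFeaturizer)
from .synth import SynthConfig, SynthDataset, generate
from .topology import TopologicalPairFeaturizer

logger = logging.getLogger("ddilink")

__all__ = ["RunConfig", "RunReport", "run", "stage_seed",
           "prepare_network_data", "evaluate_network"]

METRIC_COLUMNS = ["network", "subset", "classifier", "precision", "recall",
                  "f1", "auroc", "aupr", "fnr", "fpr", "tnr", "tpr"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Derived per-stage seed: stable hash of the root seed and stage name,
    so adding a stage never perturbs earlier stages' randomness."""
    return zlib.crc32(f"{root_seed}:{stage}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    mode: str = "paper"  # or "leakage-safe"
    train_fraction: float = 0.66
    percentile: float = 90.0
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES
    include_unsupervised: bool = True
    community_method: str = "partition-modularity"
    delta: float = 0.001
    seed: int = 0
    outdir: str | None = None
    # either synth blocks or file inputs
    synth: list[dict] = field(default_factory=list)
    networks: list[dict] = field(default_factory=list)  # name/edges/atc/mesh/ade/fingerprints paths
    n_random_pairs: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "leakage-safe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.classifiers) - set(CLASSIFIER_FAMILIES)
        if unknown:
            raise ValueError(f"unknown classifier families: {sorted(unknown)}")
        if not self.synth and not self.networks:
            raise ValueError("config must list synthetic blocks or network inputs")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "classifiers" in data:
            data["classifiers"] = tuple(data["classifiers"])
        return cls(**data)


@dataclass
class RunReport:
    """Everything one run produced, with provenance."""

    config: RunConfig
    stats: list[NetworkStats]
    metrics: pd.DataFrame
    rank_comparison: RankComparison | None
    importances: dict[str, ImportanceReport]
    group_comparisons: dict[str, GroupSimilarityComparison]
    dendrograms: dict[str, FeatureDendrogram]

    def aupr_matrix(self, subset: str = "test") -> pd.DataFrame:
        """Datasets x classifiers AUPR matrix for rank comparison."""
        sub = self.metrics[(self.metrics["subset"] == subset)
                           & (self.metrics["classifier"] != "unsupervised")]
        return sub.pivot(index="network", columns="classifier", values="aupr")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([s.to_row() for s in self.stats]).to_csv(
            outdir / "network_stats.csv", index=False)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        payload = {
            "mode": self.config.mode,
            "seed": self.config.seed,
            "rank_comparison": (self.rank_comparison.to_dict()
                                if self.rank_comparison else None),
            "group_comparisons": {
                name: {"means": g.group_means,
                       "kruskal_statistic": g.kruskal_statistic,
                       "p_value": g.p_value}
                for name, g in self.group_comparisons.items()},
            "importances": {
                name: rep.to_frame().to_dict(orient="list")
                for name, rep in self.importances.items()},
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=1))


def prepare_network_data(net: DrugNetwork, catalogs: dict, config: RunConfig):
    """Build featurized train/test labeled pair tables for one network.

    Returns ``(train, test, featurize)`` where ``featurize`` maps a bare
    pair table to a fully featurized one (used for diagnostics on random
    pairs).
    """
    seed_pairs = stage_seed(config.seed, f"pairs:{net.name}")
    seed_split = stage_seed(config.seed, f"split:{net.name}")
    sem = SemanticPairFeaturizer().fit(
        catalogs["atc"], catalogs["chem"], catalogs["mesh"], catalogs["ade"])

    if config.mode == "paper":
        topo = TopologicalPairFeaturizer(
            community_method=config.community_method, delta=config.delta,
            seed=seed_pairs).fit(net)
        pairs = build_balanced_pairs(net, seed=seed_pairs)
        features = sem.transform(topo.transform(pairs))
        train, test = partition_examples(
            features, train_frac=config.train_fraction, seed=seed_split)
    else:
        split = split_edges(net, train_frac=config.train_fraction,
                            seed=seed_split)
        train_graph = DrugNetwork.from_edges(
            split.train_edges, name=net.name + ":train", nodes=net.nodes)
        topo = TopologicalPairFeaturizer(
            community_method=config.community_method, delta=config.delta,
            seed=seed_pairs).fit(train_graph)
        # negatives drawn once against the FULL edge set, then divided
        all_pairs = build_balanced_pairs(net, seed=seed_pairs)
        negatives = all_pairs[all_pairs["label"] == 0].reset_index(drop=True)
        n_train_pos = len(split.train_edges)
        train_rows = (
            [(u, v, 1) for u, v in sorted(split.train_edges)]
            + [tuple(r) for r in negatives.iloc[:n_train_pos][
                ["drug_id_1", "drug_id_2", "label"]].itertuples(index=False)])
        test_rows = (
            [(u, v, 1) for u, v in sorted(split.test_edges)]
            + [tuple(r) for r in negatives.iloc[n_train_pos:][
                ["drug_id_1", "drug_id_2", "label"]].itertuples(index=False)])
        train = pd.DataFrame(train_rows, columns=["drug_id_1", "drug_id_2", "label"])
        test = pd.DataFrame(test_rows, columns=["drug_id_1", "drug_id_2", "label"])
        train = sem.transform(topo.transform(train))
        test = sem.transform(topo.transform(test))
    for df in (train, test):
        df.attrs["mode"] = config.mode
        df.attrs["network"] = net.name

    def featurize(bare_pairs: pd.DataFrame) -> pd.DataFrame:
        return sem.transform(topo.transform(bare_pairs))

    return train, test, featurize


def _metric_row(network: str, subset: str, classifier: str, truth,
                predicted, scores) -> dict:
    cm = confusion_metrics(truth, predicted)
    cv = curve_metrics(truth, scores)
    return {"network": network, "subset": subset, "classifier": classifier,
            "precision": cm.precision, "recall": cm.recall, "f1": cm.f1,
            "auroc": cv.auroc, "aupr": cv.aupr, "fnr": cm.fnr, "fpr": cm.fpr,
            "tnr": cm.tnr, "tpr": cm.tpr}


def evaluate_network(name: str, train: pd.DataFrame, test: pd.DataFrame,
                     config: RunConfig):
    """Fit every configured classifier on one network's train set and score
    both subsets.  Returns (metric rows, fitted models dict)."""
    feature_cols = [c for c in FEATURE_COLUMNS if c in train.columns]
    X_train, y_train = train[feature_cols], train["label"].to_numpy(int)
    X_test, y_test = test[feature_cols], test["label"].to_numpy(int)
    rows, models = [], {}
    if config.include_unsupervised:
        comb = CombinedSimilarityClassifier(percentile=config.percentile)
        comb.fit(X_train)
        models["unsupervised"] = comb
        for subset, X, y in (("train", X_train, y_train), ("test", X_test, y_test)):
            rows.append(_metric_row(name, subset, "unsupervised", y,
                                    comb.predict(X), comb.decision_function(X)))
    for family in config.classifiers:
        t0 = time.perf_counter()
        clf = TunedPairClassifier(
            family=family, seed=stage_seed(config.seed, f"clf:{name}:{family}"))
        clf.fit(X_train, y_train)
        models[family] = clf
        for subset, X, y in (("train", X_train, y_train), ("test", X_test, y_test)):
            rows.append(_metric_row(name, subset, family, y,
                                    clf.predict(X), clf.decision_function(X)))
        logger.info("%s/%s fitted in %.1fs", name, family,
                    time.perf_counter() - t0)
    return rows, models


def _load_network_block(block: dict):
    net = load_edge_list(block["edges"], name=block.get("name"))
    catalogs = {
        "atc": AttributeCatalog.from_tsv(block["atc"], "atc")
        if "atc" in block else AttributeCatalog(channel="atc"),
        "mesh": AttributeCatalog.from_tsv(block["mesh"], "mesh")
        if "mesh" in block else AttributeCatalog(channel="mesh"),
        "ade": AttributeCatalog.from_tsv(block["ade"], "ade")
        if "ade" in block else AttributeCatalog(channel="ade"),
        "chem": FingerprintCatalog.from_tsv(block["fingerprints"])
        if "fingerprints" in block else FingerprintCatalog(),
    }
    return net, catalogs


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Deterministic given the config's seed; per-stage randomness is derived
    with :func:`stage_seed`.
    """
    datasets: list[tuple[DrugNetwork, dict]] = []
    for i, block in enumerate(config.synth):
        params = {k: v for k, v in block.items() if k != "name"}
        params.setdefault("seed", stage_seed(config.seed, f"synth:{i}"))
        ds: SynthDataset = generate(SynthConfig(**params))
        if "name" in block:
            ds.network.name = block["name"]
        datasets.append((ds.network, ds.catalogs()))
    for block in config.networks:
        datasets.append(_load_network_block(block))

    stats, metric_rows = [], []
    importances: dict[str, ImportanceReport] = {}
    group_comparisons: dict[str, GroupSimilarityComparison] = {}
    dendrograms: dict[str, FeatureDendrogram] = {}
    for net, catalogs in datasets:
        t0 = time.perf_counter()
        stats.append(network_stats(net))
        train, test, featurize = prepare_network_data(net, catalogs, config)
        rows, models = evaluate_network(net.name, train, test, config)
        metric_rows.extend(rows)
        feature_cols = [c for c in FEATURE_COLUMNS if c in train.columns]
        for family in ("random_forest", "gbm"):
            if family in models:
                importances[f"{net.name}:{family}"] = feature_importance(
                    models[family], feature_names=feature_cols)
        combined = pd.concat([train, test], ignore_index=True)
        group_comparisons[net.name] = group_similarity_comparison(
            combined, net, feature_cols, n_random=config.n_random_pairs,
            seed=stage_seed(config.seed, f"random-pairs:{net.name}"),
            featurizer=featurize)
        dendrograms[net.name] = feature_dendrogram(combined, feature_cols)
        logger.info("network %s done in %.1fs", net.name,
                    time.perf_counter() - t0)

    metrics = pd.DataFrame(metric_rows, columns=METRIC_COLUMNS)
    rank_comparison = None
    supervised = metrics[(metrics["subset"] == "test")
                         & (metrics["classifier"] != "unsupervised")]
    if supervised["network"].nunique() >= 2 and \
            supervised["classifier"].nunique() >= 2:
        matrix = supervised.pivot(index="network", columns="classifier",
                                  values="aupr")
        rank_comparison = compare_classifiers(matrix)
    report = RunReport(config=config, stats=stats, metrics=metrics,
                       rank_comparison=rank_comparison,
                       importances=importances,
                       group_comparisons=group_comparisons,
                       dendrograms=dendrograms)
    if config.outdir:
        report.write(config.outdir)
    return report
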