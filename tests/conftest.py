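import numpy as np
import pandas as pd
import pytest

import ddilink as dl


@pytest.fixture
def toy_net():
    """Five-edge graph used throughout the index examples:
    edges a-c, b-c, a-d, b-d, c-d."""
    return dl.DrugNetwork.from_edges(
        [("a", "c"), ("b", "c"), ("a", "d"), ("b", "d"), ("c", "d")],
        name="toy")


@pytest.fixture
def triangle(tmp_path):
    path = tmp_path / "triangle.tsv"
    path.write_text("a\tb\nb\tc\na\tc\n")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """Small full-signal synthetic dataset shared by evaluator/model tests."""
    cfg = dl.SynthConfig(n_drugs=200, n_communities=4, p_in=0.25, p_out=0.02,
                         seed=11)
    return dl.generate(cfg)


@pytest.fixture(scope="session")
def featurized_pairs(small_dataset):
    """Balanced labeled pairs of the small dataset with all 12 features."""
    ds = small_dataset
    pairs = dl.build_balanced_pairs(ds.network, seed=5)
    topo = dl.TopologicalPairFeaturizer().fit(ds.network)
    sem = dl.SemanticPairFeaturizer().fit(ds.atc, ds.fingerprints, ds.mesh,
                                          ds.ade)
    return sem.transform(topo.transform(pairs))


def random_graph(rng: np.random.Generator, n_max: int = 30):
    """Erdos-Renyi-style random test graph with string node ids."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return dl.DrugNetwork.from_edges(edges, name="rand", nodes=nodes)
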