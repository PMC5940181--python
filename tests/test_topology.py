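"""Topological pair-similarity indices and community detection."""

import math

import networkx as nx
import numpy as np
import pytest

import ddilink as dl
from ddilink.topology import (CLASSICAL_KINDS, TOPO_FEATURES,
                              CommunityAssignment, NeighborhoodIndex,
                              classical_index, community_index, pair_features)

from conftest import random_graph


def brute_force_indices(edge_set, x, y, comm, delta):
    """Independent oracle: all eight indices from raw set arithmetic over
    the edge list, no shared code with the implementation."""
    nbrs = {}
    for u, v in edge_set:
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    gx = nbrs.get(x, set())
    gy = nbrs.get(y, set())
    common = gx & gy
    union = gx | gy
    deg = lambda z: len(nbrs.get(z, set()))
    cx, cy = comm.overlapping[x], comm.overlapping[y]
    shared = lambda i: len(comm.overlapping[i] & cx & cy)
    within = sum(1 for i in common
                 if comm.partition[i] == comm.partition[x] == comm.partition[y])
    inter = len(common) - within
    return {
        "cn": float(len(common)),
        "jc": len(common) / len(union) if union else 0.0,
        "aai": sum(1.0 / math.log(deg(z)) for z in common),
        "pa": float(len(gx) * len(gy)),
        "rai": sum(1.0 / deg(z) for z in common),
        "ccn": len(common) + sum(shared(i) for i in common),
        "cra": sum((1 + shared(i)) / deg(i) for i in common),
        "wic": within / (inter + delta),
    }


@pytest.fixture
def toy_index(toy_net):
    return NeighborhoodIndex.from_network(toy_net)


@pytest.fixture
def one_community(toy_net):
    nodes = toy_net.nodes
    return CommunityAssignment(
        overlapping={n: frozenset([0]) for n in nodes},
        partition={n: 0 for n in nodes})


class TestClassicalIndices:
    def test_worked_example(self, toy_index):
        assert classical_index("cn", "a", "b", toy_index) == 2
        assert classical_index("jc", "a", "b", toy_index) == 1.0
        assert classical_index("pa", "a", "b", toy_index) == 4
        assert classical_index("rai", "a", "b", toy_index) == pytest.approx(2 / 3)
        assert classical_index("aai", "a", "b", toy_index) == pytest.approx(
            2 / math.log(3))

    def test_no_common_neighbors(self, toy_index):
        net = dl.DrugNetwork.from_edges([("a", "b"), ("c", "d")])
        idx = NeighborhoodIndex.from_network(net)
        assert classical_index("cn", "a", "c", idx) == 0
        assert classical_index("jc", "a", "c", idx) == 0
        assert classical_index("aai", "a", "c", idx) == 0
        assert classical_index("rai", "a", "c", idx) == 0
        assert classical_index("pa", "a", "c", idx) == 1

    def test_same_node_rejected(self, toy_index):
        with pytest.raises(ValueError):
            classical_index("cn", "a", "a", toy_index)

    def test_unknown_node_rejected(self, toy_index):
        with pytest.raises(KeyError):
            classical_index("cn", "a", "zzz", toy_index)


class TestCommunityIndices:
    def test_worked_example_single_community(self, toy_index, one_community):
        assert community_index("ccn", "a", "b", toy_index, one_community) == 4
        assert community_index("cra", "a", "b", toy_index,
                               one_community) == pytest.approx(4 / 3)
        assert community_index("wic", "a", "b", toy_index, one_community,
                               delta=0.001) == pytest.approx(2000.0)

    def test_collapse_without_shared_communities(self, toy_index, toy_net):
        # every node its own community: no community shared by x, y and i
        comm = CommunityAssignment(
            overlapping={n: frozenset([i]) for i, n in enumerate(toy_net.nodes)},
            partition={n: i for i, n in enumerate(toy_net.nodes)})
        assert community_index("ccn", "a", "b", toy_index, comm) == \
            classical_index("cn", "a", "b", toy_index)
        assert community_index("cra", "a", "b", toy_index, comm) == \
            pytest.approx(classical_index("rai", "a", "b", toy_index))

    def test_wic_zero_across_partitions(self, toy_index, toy_net):
        partition = {n: (0 if n in ("a", "c") else 1) for n in toy_net.nodes}
        comm = CommunityAssignment(
            overlapping={n: frozenset([c]) for n, c in partition.items()},
            partition=partition)
        assert community_index("wic", "a", "b", toy_index, comm) == 0.0

    def test_single_global_community_identities(self, toy_index, one_community):
        """With one community: wic = cn/delta and ccn = 2 cn."""
        for x, y in [("a", "b"), ("c", "d"), ("a", "d")]:
            cn = classical_index("cn", x, y, toy_index)
            assert community_index("wic", x, y, toy_index, one_community,
                                   delta=0.5) == pytest.approx(cn / 0.5)
            assert community_index("ccn", x, y, toy_index,
                                   one_community) == 2 * cn

    def test_nonpositive_delta_rejected(self, toy_index, one_community):
        with pytest.raises(ValueError):
            community_index("wic", "a", "b", toy_index, one_community, delta=0)


class TestOracleAgreement:
    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            net = random_graph(rng, n_max=20)
            if net.n_edges < 2:
                continue
            comm = dl.detect_communities(net)
            idx = NeighborhoodIndex.from_network(net)
            nodes = net.nodes
            for _ in range(10):
                i, j = rng.choice(len(nodes), size=2, replace=False)
                x, y = nodes[i], nodes[j]
                expected = brute_force_indices(net.edge_set(), x, y, comm, 0.001)
                got = pair_features(x, y, idx, comm, delta=0.001)
                for kind in TOPO_FEATURES:
                    assert got[kind] == pytest.approx(expected[kind], abs=1e-9)

    def test_against_networkx_reference(self):
        """Cross-check the five classical and three community indices against
        the networkx reference implementations (partition view)."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            net = random_graph(rng, n_max=20)
            if net.n_edges < 2:
                continue
            comm = dl.detect_communities(net)
            g = net.graph.copy()
            nx.set_node_attributes(g, comm.partition, "community")
            idx = NeighborhoodIndex.from_network(net)
            nodes = net.nodes
            pairs = [(nodes[a], nodes[b]) for a, b in
                     rng.choice(len(nodes), size=(8, 2)) if a != b]
            if not pairs:
                continue
            # (cra is not cross-checked: the networkx variant scores only
            # community-sharing neighbors, without the 1/d baseline term)
            for fn, kind in [(nx.jaccard_coefficient, "jc"),
                             (nx.adamic_adar_index, "aai"),
                             (nx.preferential_attachment, "pa"),
                             (nx.resource_allocation_index, "rai"),
                             (nx.cn_soundarajan_hopcroft, "ccn")]:
                for u, v, ref in fn(g, pairs):
                    mine = pair_features(u, v, idx, comm)[kind]
                    assert mine == pytest.approx(ref, abs=1e-9)
            for u, v, ref in nx.within_inter_cluster(g, pairs, delta=0.001):
                mine = community_index("wic", u, v, idx, comm, delta=0.001)
                assert mine == pytest.approx(ref, abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            net = random_graph(rng, n_max=25)
            if net.n_edges < 2:
                continue
            comm = dl.detect_communities(net)
            idx = NeighborhoodIndex.from_network(net)
            nodes = net.nodes
            for _ in range(10):
                i, j = rng.choice(len(nodes), size=2, replace=False)
                x, y = nodes[i], nodes[j]
                f = pair_features(x, y, idx, comm)
                g = pair_features(y, x, idx, comm)
                for kind in TOPO_FEATURES:
                    assert f[kind] == pytest.approx(g[kind], abs=1e-12)
                assert 0.0 <= f["jc"] <= 1.0
                assert f["rai"] <= f["cn"] / 2 + 1e-12
                assert f["aai"] <= f["cn"] / math.log(2) + 1e-12
                assert f["ccn"] >= f["cn"]
                assert f["cra"] >= f["rai"] - 1e-12
                assert f["wic"] >= 0.0


class TestDetectCommunities:
    def test_two_cliques_recovered(self):
        edges = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
        edges += [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
        edges += [("a0", "b0")]  # single bridge keeps it connected
        net = dl.DrugNetwork.from_edges(edges)
        comm = dl.detect_communities(net)
        groups = {}
        for node, cid in comm.partition.items():
            groups.setdefault(cid, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]]

    def test_every_node_assigned(self):
        net = dl.DrugNetwork.from_edges([("a", "b")], nodes=["a", "b", "c"])
        comm = dl.detect_communities(net)
        assert set(comm.partition) == {"a", "b", "c"}
        assert all(len(comm.overlapping[n]) >= 1 for n in ("a", "b", "c"))

    def test_determinism(self, small_dataset):
        a = dl.detect_communities(small_dataset.network, seed=1)
        b = dl.detect_communities(small_dataset.network, seed=1)
        assert a.partition == b.partition

    def test_overlapping_clique_view(self, toy_net):
        comm = dl.detect_communities(toy_net, method="overlapping-clique")
        assert set(comm.partition) == set(toy_net.nodes)
        # the partition view must agree with some overlapping membership
        for n in toy_net.nodes:
            assert comm.partition[n] in comm.overlapping[n]

    def test_unknown_method_rejected(self, toy_net):
        with pytest.raises(ValueError):
            dl.detect_communities(toy_net, method="spectral")


class TestFeaturizer:
    def test_column_order(self, toy_net):
        import pandas as pd
        pairs = pd.DataFrame({"drug_id_1": ["a"], "drug_id_2": ["b"],
                              "label": [1]})
        out = dl.featurize_pairs(pairs, toy_net)
        assert list(out.columns) == ["drug_id_1", "drug_id_2", "label",
                                     "cn", "jc", "aai", "pa", "rai",
                                     "ccn", "cra", "wic"]

    def test_isolated_pair_all_zero(self):
        import pandas as pd
        net = dl.DrugNetwork.from_edges([("a", "b")], nodes=["a", "b", "x", "y"])
        pairs = pd.DataFrame({"drug_id_1": ["x"], "drug_id_2": ["y"],
                              "label": [0]})
        out = dl.featurize_pairs(pairs, net)
        assert (out[list(TOPO_FEATURES)].to_numpy() == 0).all()

    def test_missing_endpoint_is_an_error(self, toy_net):
        import pandas as pd
        pairs = pd.DataFrame({"drug_id_1": ["a"], "drug_id_2": ["nope"],
                              "label": [0]})
        with pytest.raises(KeyError, match="nope"):
            dl.featurize_pairs(pairs, toy_net)
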