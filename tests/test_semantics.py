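"""IDF-weighted cosine similarities and fingerprint Tanimoto."""

import math

import numpy as np
import pandas as pd
import pytest

import ddilink as dl
from ddilink.semantics import AttributeCatalog, FingerprintCatalog


@pytest.fixture
def tiny_catalog():
    return AttributeCatalog(channel="atc", codes={
        "d1": {"A", "B"}, "d2": {"A"}, "d3": {"C"}})


class TestIdf:
    def test_universal_code_weight_zero(self):
        cat = AttributeCatalog(channel="atc", codes={
            f"d{i}": {"X"} for i in range(10)})
        assert dl.compute_idf(cat)["X"] == 0.0

    def test_rare_code_weight(self, tiny_catalog):
        assert dl.compute_idf(tiny_catalog)["B"] == pytest.approx(math.log(3))

    def test_weights_decrease_with_frequency(self):
        for n_drugs in range(2, 21):
            weights = []
            for n_t in range(1, n_drugs + 1):
                codes = {f"d{i}": ({"T"} if i < n_t else {"other"})
                         for i in range(n_drugs)}
                cat = AttributeCatalog(channel="mesh", codes=codes)
                weights.append(dl.compute_idf(cat).get("T"))
            assert all(a > b for a, b in zip(weights, weights[1:]))


class TestIdfCosine:
    def test_identical_sets(self, tiny_catalog):
        sim, missing = dl.idf_cosine("d1", "d1", tiny_catalog)
        assert sim == pytest.approx(1.0)
        assert not missing

    def test_disjoint_sets(self, tiny_catalog):
        sim, missing = dl.idf_cosine("d1", "d3", tiny_catalog)
        assert sim == 0.0 and not missing

    def test_worked_example(self, tiny_catalog):
        w_a, w_b = math.log(1.5), math.log(3)
        expected = w_a ** 2 / (math.sqrt(w_a ** 2 + w_b ** 2) * w_a)
        sim, _ = dl.idf_cosine("d1", "d2", tiny_catalog)
        assert sim == pytest.approx(expected)
        assert sim == pytest.approx(0.3463, abs=1e-4)

    def test_absent_drug_flagged(self, tiny_catalog):
        sim, missing = dl.idf_cosine("d1", "ghost", tiny_catalog)
        assert sim == 0.0 and missing

    def test_zero_norm_vector_flagged(self):
        cat = AttributeCatalog(channel="atc",
                               codes={"d1": {"X"}, "d2": {"X"}})
        # X appears everywhere -> weight 0 -> zero-norm weighted vectors
        sim, missing = dl.idf_cosine("d1", "d2", cat)
        assert sim == 0.0 and missing

    def test_irrelevant_vocabulary_invariance(self, tiny_catalog):
        base, _ = dl.idf_cosine("d1", "d2", tiny_catalog)
        bigger = AttributeCatalog(channel="atc", codes={
            **{k: set(v) for k, v in tiny_catalog.codes.items()},
            "d4": {"Z1", "Z2", "Z3"}})
        # adding codes owned by neither d1 nor d2 changes |D| (hence all
        # weights uniformly through the log) but only slightly perturbs the
        # relative weighting; invariance is exact when |D| is held fixed
        same_universe = AttributeCatalog(channel="atc", codes={
            "d1": {"A", "B"}, "d2": {"A"}, "d3": {"C", "Z9"}})
        sim, _ = dl.idf_cosine("d1", "d2", same_universe)
        assert sim == pytest.approx(base)

    def test_matches_explicit_vector_arithmetic(self):
        rng = np.random.default_rng(13)
        vocab = [f"c{t}" for t in range(30)]
        for _ in range(50):
            n_drugs = int(rng.integers(3, 15))
            codes = {}
            for i in range(n_drugs):
                k = int(rng.integers(1, 8))
                codes[f"d{i}"] = set(rng.choice(vocab, size=k, replace=False))
            cat = AttributeCatalog(channel="ade", codes=codes)
            weights = dl.compute_idf(cat)
            x, y = "d0", "d1"
            vx = np.array([weights.get(t, 0.0) * (t in codes[x]) for t in vocab])
            vy = np.array([weights.get(t, 0.0) * (t in codes[y]) for t in vocab])
            nx_, ny = np.linalg.norm(vx), np.linalg.norm(vy)
            sim, missing = dl.idf_cosine(x, y, cat, weights)
            if nx_ == 0 or ny == 0:
                assert sim == 0.0 and missing
            else:
                assert sim == pytest.approx(vx @ vy / (nx_ * ny), abs=1e-12)

    def test_symmetry(self, tiny_catalog):
        assert dl.idf_cosine("d1", "d2", tiny_catalog) == \
            dl.idf_cosine("d2", "d1", tiny_catalog)


class TestTanimoto:
    def make_catalog(self, fps, n_bits):
        return FingerprintCatalog(
            fingerprints={k: np.array(v, dtype=np.uint8) for k, v in fps.items()},
            n_bits=n_bits)

    def test_identical_nonzero(self):
        cat = self.make_catalog({"x": [1, 1, 0, 0], "y": [1, 1, 0, 0]}, 4)
        assert dl.tanimoto("x", "y", cat) == (1.0, False)

    def test_worked_example(self):
        cat = self.make_catalog({"x": [1, 1, 0, 0], "y": [1, 0, 1, 0]}, 4)
        sim, _ = dl.tanimoto("x", "y", cat)
        assert sim == pytest.approx(1 / 3)

    def test_both_zero_flagged(self):
        cat = self.make_catalog({"x": [0, 0], "y": [0, 0]}, 2)
        assert dl.tanimoto("x", "y", cat) == (0.0, True)

    def test_random_pairs_match_bit_counting_and_jaccard(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            fx = (rng.random(64) < 0.2).astype(np.uint8)
            fy = (rng.random(64) < 0.2).astype(np.uint8)
            cat = self.make_catalog({"x": fx, "y": fy}, 64)
            sim, missing = dl.tanimoto("x", "y", cat)
            # per-bit loop oracle
            a = b = c = 0
            for i in range(64):
                a += fx[i] == 1
                b += fy[i] == 1
                c += fx[i] == 1 and fy[i] == 1
            if a + b - c == 0:
                assert sim == 0.0 and missing
                continue
            assert sim == pytest.approx(c / (a + b - c), abs=1e-12)
            # Jaccard-on-supports equivalence
            sx = {i for i in range(64) if fx[i]}
            sy = {i for i in range(64) if fy[i]}
            assert sim == pytest.approx(len(sx & sy) / len(sx | sy), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FingerprintCatalog(fingerprints={"x": np.ones(8, dtype=np.uint8)},
                               n_bits=4)


class TestSemanticFeaturizer:
    def test_missing_channel_imputed_zero(self, tiny_catalog):
        fp = FingerprintCatalog(fingerprints={}, n_bits=8)
        empty = AttributeCatalog(channel="mesh")
        feat = dl.SemanticPairFeaturizer().fit(tiny_catalog, fp, empty, empty)
        pairs = pd.DataFrame({"drug_id_1": ["d1"], "drug_id_2": ["d2"],
                              "label": [1]})
        out = feat.transform(pairs)
        assert out.loc[0, "chem"] == 0.0
        assert out.loc[0, "mesh"] == 0.0
        assert feat.missing_counts_["chem"] == 1
        assert out.loc[0, "atc"] > 0

    def test_duplicate_drugs_score_one_everywhere(self):
        codes = {"d1": {"A", "B"}, "d2": {"A", "B"}, "d3": {"C"}}
        cats = [AttributeCatalog(channel=ch, codes=codes)
                for ch in ("atc", "mesh", "ade")]
        fp = FingerprintCatalog(fingerprints={
            "d1": np.array([1, 0, 1, 0], dtype=np.uint8),
            "d2": np.array([1, 0, 1, 0], dtype=np.uint8)}, n_bits=4)
        feat = dl.SemanticPairFeaturizer().fit(cats[0], fp, cats[1], cats[2])
        pairs = pd.DataFrame({"drug_id_1": ["d1"], "drug_id_2": ["d2"],
                              "label": [1]})
        out = feat.transform(pairs)
        for col in ("atc", "chem", "mesh", "ade"):
            assert out.loc[0, col] == pytest.approx(1.0)

    def test_rows_match_single_pair_recomputation(self, small_dataset):
        ds = small_dataset
        pairs = dl.build_balanced_pairs(ds.network, seed=17).head(40)
        feat = dl.SemanticPairFeaturizer().fit(ds.atc, ds.fingerprints,
                                               ds.mesh, ds.ade)
        out = feat.transform(pairs)
        idf = {ch: dl.compute_idf(getattr(ds, ch)) for ch in ("atc", "mesh", "ade")}
        for _, row in out.iterrows():
            u, v = row["drug_id_1"], row["drug_id_2"]
            for ch in ("atc", "mesh", "ade"):
                ref, _ = dl.idf_cosine(u, v, getattr(ds, ch), idf[ch])
                assert row[ch] == pytest.approx(ref, abs=1e-12)
            ref, _ = dl.tanimoto(u, v, ds.fingerprints)
            assert row["chem"] == pytest.approx(ref, abs=1e-12)


class TestCatalogIO:
    def test_attribute_round_trip(self, tmp_path, tiny_catalog):
        path = tmp_path / "atc.tsv"
        tiny_catalog.to_tsv(path)
        loaded = AttributeCatalog.from_tsv(path, "atc")
        assert loaded.codes == tiny_catalog.codes

    def test_first_level_truncation(self, tmp_path):
        path = tmp_path / "atc.tsv"
        path.write_text("drug_id\tcode\nd1\tA01AB\nd1\tA02BC\nd2\tB01AA\n")
        full = AttributeCatalog.from_tsv(path, "atc")
        trunc = AttributeCatalog.from_tsv(path, "atc",
                                          truncate_to_first_level=True)
        assert full.codes["d1"] == frozenset({"A01AB", "A02BC"})
        assert trunc.codes["d1"] == frozenset({"A"})
        assert trunc.codes["d2"] == frozenset({"B"})

    def test_fingerprint_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "fp.tsv"
        small_dataset.fingerprints.to_tsv(path)
        loaded = FingerprintCatalog.from_tsv(path)
        assert loaded.n_bits == small_dataset.fingerprints.n_bits
        for drug, bits in small_dataset.fingerprints.fingerprints.items():
            assert (loaded.fingerprints[drug] == bits).all()
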