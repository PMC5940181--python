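"""Semantic pair similarities: IDF-weighted cosine and Tanimoto.

Three attribute channels (therapeutic ATC codes, MeSH indexing terms,
side-effect/ADE terms) represent each drug as a binary code vector; codes
are down-weighted by inverse document frequency IDF(t) = ln(|D| / n_t)
where |D| is the catalog's compound count and n_t the number of compounds
carrying code t.  Pair similarity on a channel is the cosine of the two
IDF-weighted vectors.  The chemical channel compares fixed-length binary
fingerprints with the Tanimoto coefficient c / (a + b - c), which equals
the Jaccard similarity of the supported-bit sets.

A drug missing from a channel (or with an empty/zero vector) scores 0 on
that channel with a missing flag; missingness is data, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AttributeCatalog",
    "FingerprintCatalog",
    "compute_idf",
    "idf_cosine",
    "tanimoto",
    "SemanticPairFeaturizer",
    "featurize_pairs_semantic",
    "SEMANTIC_FEATURES",
]

SEMANTIC_FEATURES = ("atc", "chem", "mesh", "ade")


@dataclass
class AttributeCatalog:
    """Per-drug code sets for one attribute channel (ATC / MESH / ADE).

    Drugs with an explicitly empty set are recorded and distinguishable
    from drugs absent from the catalog.
    """

    channel: str
    codes: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = {d: frozenset(c) for d, c in self.codes.items()}

    @property
    def vocabulary(self) -> frozenset:
        return frozenset(c for s in self.codes.values() for c in s)

    @property
    def n_drugs(self) -> int:
        return len(self.codes)

    def __contains__(self, drug: str) -> bool:
        return drug in self.codes

    @classmethod
    def from_tsv(cls, path: str | Path, channel: str,
                 truncate_to_first_level: bool = False) -> "AttributeCatalog":
        """Read a long-format headered TSV (drug_id, code).

        ``truncate_to_first_level`` keeps only the first character of each
        code — the anatomical main group for ATC-style hierarchical codes.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (drug_id, code)")
        drug_col, code_col = df.columns[:2]
        codes: dict[str, set] = {}
        for drug, code in zip(df[drug_col], df[code_col]):
            value = code[:1] if truncate_to_first_level else code
            codes.setdefault(drug, set()).add(value)
        return cls(channel=channel, codes={d: frozenset(s) for d, s in codes.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [(d, c) for d in sorted(self.codes) for c in sorted(self.codes[d])]
        pd.DataFrame(rows, columns=["drug_id", "code"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class FingerprintCatalog:
    """Per-drug fixed-length binary fingerprints (default 1024 bits)."""

    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)
    n_bits: int = 1024

    def __post_init__(self) -> None:
        fps = {}
        for drug, bits in self.fingerprints.items():
            arr = np.asarray(bits, dtype=np.uint8)
            if arr.ndim != 1 or arr.size != self.n_bits:
                raise ValueError(
                    f"fingerprint for {drug!r} has length {arr.size}, "
                    f"expected {self.n_bits}")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"fingerprint for {drug!r} has non-binary entries")
            fps[drug] = arr
        self.fingerprints = fps

    def __contains__(self, drug: str) -> bool:
        return drug in self.fingerprints

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FingerprintCatalog":
        """Read a headered TSV (drug_id, bitstring of 0/1 characters)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        drug_col, bits_col = df.columns[:2]
        raw = {d: np.frombuffer(b.encode(), dtype=np.uint8) - ord("0")
               for d, b in zip(df[drug_col], df[bits_col])}
        lengths = {a.size for a in raw.values()}
        if len(lengths) > 1:
            raise ValueError(f"{path}: fingerprints of mixed lengths {sorted(lengths)}")
        n_bits = lengths.pop() if lengths else 1024
        return cls(fingerprints=raw, n_bits=n_bits)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(d, "".join(map(str, self.fingerprints[d])))
                for d in sorted(self.fingerprints)]
        pd.DataFrame(rows, columns=["drug_id", "bits"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_smiles(cls, smiles: dict[str, str], n_bits: int = 1024) -> "FingerprintCatalog":
        """Optional adapter: Morgan (extended-connectivity) fingerprints
        from SMILES strings; requires the rdkit extra."""
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        fps = {}
        for drug, smi in smiles.items():
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES for {drug!r}: {smi!r}")
            fps[drug] = np.array(gen.GetFingerprint(mol), dtype=np.uint8)
        return cls(fingerprints=fps, n_bits=n_bits)


def compute_idf(catalog: AttributeCatalog) -> dict[str, float]:
    """IDF weight ln(|D| / n_t) for every vocabulary code.

    |D| is the number of drugs recorded in this channel's catalog (channel-
    specific, not the network's node count).
    """
    n_drugs = catalog.n_drugs
    if n_drugs < 1:
        raise ValueError("catalog has no drugs")
    counts: dict[str, int] = {}
    for code_set in catalog.codes.values():
        for code in code_set:
            counts[code] = counts.get(code, 0) + 1
    return {code: math.log(n_drugs / n_t) for code, n_t in counts.items()}


def idf_cosine(x: str, y: str, catalog: AttributeCatalog,
               weights: dict[str, float] | None = None) -> tuple[float, bool]:
    """Cosine similarity of the IDF-weighted binary code vectors of x and y.

    Returns ``(similarity, missing_flag)``; similarity is 0 with the flag
    set when either drug is absent from the catalog or has a zero-norm
    weighted vector (e.g. only codes shared by every drug).
    """
    if x not in catalog or y not in catalog:
        return 0.0, True
    if weights is None:
        weights = compute_idf(catalog)
    cx, cy = catalog.codes[x], catalog.codes[y]
    norm_x = math.sqrt(sum(weights[c] ** 2 for c in cx))
    norm_y = math.sqrt(sum(weights[c] ** 2 for c in cy))
    if norm_x == 0.0 or norm_y == 0.0:
        return 0.0, True
    dot = sum(weights[c] ** 2 for c in cx & cy)
    return dot / (norm_x * norm_y), False


def tanimoto(x: str, y: str, catalog: FingerprintCatalog) -> tuple[float, bool]:
    """Tanimoto coefficient c/(a+b-c) over the two drugs' fingerprints.

    ``a`` and ``b`` are the set-bit counts of each fingerprint and ``c``
    the count of bits set in both.  Returns ``(similarity, missing_flag)``;
    0 with the flag when either fingerprint is absent or both are all-zero.
    """
    if x not in catalog or y not in catalog:
        return 0.0, True
    fx, fy = catalog.fingerprints[x], catalog.fingerprints[y]
    a = int(fx.sum())
    b = int(fy.sum())
    c = int((fx & fy).sum())
    if a + b - c == 0:
        return 0.0, True
    return c / (a + b - c), False


class SemanticPairFeaturizer:
    """Transformer appending the four semantic feature columns
    (atc, chem, mesh, ade) to a labeled pair table.

    ``fit`` takes the three attribute catalogs and the fingerprint catalog
    and precomputes IDF weights; ``transform`` appends the similarity
    columns, imputing 0 for missing channels and accumulating a missingness
    summary in ``missing_counts_``.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "SemanticPairFeaturizer":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, atc: AttributeCatalog, chem: FingerprintCatalog,
            mesh: AttributeCatalog, ade: AttributeCatalog) -> "SemanticPairFeaturizer":
        self.catalogs_ = {"atc": atc, "mesh": mesh, "ade": ade}
        self.fingerprints_ = chem
        self.idf_ = {name: compute_idf(cat) if cat.n_drugs else {}
                     for name, cat in self.catalogs_.items()}
        self.missing_counts_ = {name: 0 for name in SEMANTIC_FEATURES}
        return self

    def transform(self, pairs: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "catalogs_"):
            raise RuntimeError("featurizer is not fitted; call fit(catalogs) first")
        cols: dict[str, list[float]] = {name: [] for name in SEMANTIC_FEATURES}
        missing = {name: 0 for name in SEMANTIC_FEATURES}
        for u, v in zip(pairs["drug_id_1"], pairs["drug_id_2"]):
            for name in ("atc", "mesh", "ade"):
                value, flag = idf_cosine(u, v, self.catalogs_[name], self.idf_[name])
                cols[name].append(value)
                missing[name] += flag
            value, flag = tanimoto(u, v, self.fingerprints_)
            cols["chem"].append(value)
            missing["chem"] += flag
        for name in SEMANTIC_FEATURES:
            self.missing_counts_[name] += missing[name]
        feats = pd.DataFrame({name: cols[name] for name in SEMANTIC_FEATURES},
                             index=pairs.index)
        out = pd.concat([pairs.reset_index(drop=True),
                         feats.reset_index(drop=True)], axis=1)
        out.attrs.update(pairs.attrs)
        out.attrs["semantic_missing"] = dict(missing)
        return out

    def fit_transform(self, pairs: pd.DataFrame, atc, chem, mesh, ade) -> pd.DataFrame:
        return self.fit(atc, chem, mesh, ade).transform(pairs)


def featurize_pairs_semantic(pairs: pd.DataFrame, atc: AttributeCatalog,
                             chem: FingerprintCatalog, mesh: AttributeCatalog,
                             ade: AttributeCatalog) -> pd.DataFrame:
    """Functional wrapper over :class:`SemanticPairFeaturizer`."""
    return SemanticPairFeaturizer().fit(atc, chem, mesh, ade).transform(pairs)
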