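"""Evaluation: classification metrics, cross-network rank comparison,
group similarity contrast and feature clustering.

The classifier comparison follows the repeated-measures rank framework:
within each dataset the methods are ranked by a performance metric (rank 1
= best, average ranks on ties), the Friedman chi-square

    chi2 = 12 N / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2

tests the null that all k methods are equivalent across the N datasets
(classic statistic, no tie correction), and the Nemenyi post-hoc test
compares mean ranks pairwise against the studentized-range distribution;
mean-rank differences below the critical difference

    CD = q_alpha * sqrt(k (k+1) / (6 N))

are not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .network import DrugNetwork
from .sampling import _sample_negatives

__all__ = [
    "ConfusionSummary",
    "CurveSummary",
    "RankComparison",
    "GroupSimilarityComparison",
    "FeatureDendrogram",
    "confusion_metrics",
    "curve_metrics",
    "friedman_test",
    "nemenyi_posthoc",
    "compare_classifiers",
    "group_similarity_comparison",
    "feature_dendrogram",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts and derived rates.

    Ratios with a zero denominator are NaN (undefined), never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "precision", "recall", "f1",
                 "tpr", "fpr", "tnr", "fnr")}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(truth, predicted) -> ConfusionSummary:
    """Precision/recall/F1 and the four classification rates from hard labels."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(((t == 1) & (p == 1)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    fpr = _ratio(fp, fp + tn)
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f1=f1,
        tpr=recall, fpr=fpr,
        tnr=1.0 - fpr if not math.isnan(fpr) else math.nan,
        fnr=1.0 - recall if not math.isnan(recall) else math.nan,
    )


@dataclass(frozen=True)
class CurveSummary:
    """Areas under the ROC and precision-recall curves with their points."""

    auroc: float
    aupr: float
    roc_points: np.ndarray  # columns fpr, tpr
    pr_points: np.ndarray  # columns recall, precision


def curve_metrics(truth, scores) -> CurveSummary:
    """AUROC and AUPR by trapezoidal integration over distinct thresholds.

    Equal scores are grouped into a single threshold step.  Raises when the
    truth vector contains a single class.
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {s.shape}")
    if np.unique(t).size < 2:
        raise ValueError("both classes must be present for curve metrics")
    fpr, tpr, _ = roc_curve(t, s)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(t, s)
    # precision_recall_curve returns points from high threshold to low;
    # integrate trapezoidally over recall
    aupr = float(auc(recall, precision))
    return CurveSummary(auroc=auroc, aupr=aupr,
                        roc_points=np.column_stack([fpr, tpr]),
                        pr_points=np.column_stack([recall, precision]))


@dataclass
class RankComparison:
    """Friedman omnibus + Nemenyi pairwise comparison of methods across datasets."""

    methods: tuple[str, ...]
    datasets: tuple[str, ...]
    performance: np.ndarray  # datasets x methods
    ranks: np.ndarray  # datasets x methods, 1 = best
    mean_ranks: np.ndarray
    friedman_chi2: float
    df: int
    p_value: float
    nemenyi_p: np.ndarray | None = None
    critical_difference: float | None = None
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str, float]]:
        """Method pairs whose Nemenyi p-value falls below alpha."""
        if self.nemenyi_p is None:
            raise RuntimeError("run nemenyi_posthoc first")
        out = []
        k = len(self.methods)
        for i in range(k):
            for j in range(i + 1, k):
                if self.nemenyi_p[i, j] < self.alpha:
                    out.append((self.methods[i], self.methods[j],
                                float(self.nemenyi_p[i, j])))
        return out

    def to_dict(self) -> dict:
        out = {
            "methods": list(self.methods),
            "datasets": list(self.datasets),
            "mean_ranks": self.mean_ranks.tolist(),
            "friedman_chi2": self.friedman_chi2,
            "df": self.df,
            "p_value": self.p_value,
        }
        if self.nemenyi_p is not None:
            out["nemenyi_p"] = self.nemenyi_p.tolist()
            out["critical_difference"] = self.critical_difference
            out["alpha"] = self.alpha
        return out


def friedman_test(performance, methods=None, datasets=None,
                  larger_is_better: bool = True) -> RankComparison:
    """Classic Friedman rank test over a datasets x methods matrix.

    Within each dataset the best method gets rank 1 (ties share average
    ranks); chi2 = 12N/(k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2 with df = k-1
    and the p-value from the chi-square distribution.  No tie-correction
    factor is applied.
    """
    if isinstance(performance, pd.DataFrame):
        methods = methods or list(performance.columns)
        datasets = datasets or list(performance.index)
        perf = performance.to_numpy(dtype=float)
    else:
        perf = np.asarray(performance, dtype=float)
    if perf.ndim != 2:
        raise ValueError("performance must be a 2-D datasets x methods matrix")
    n_datasets, k = perf.shape
    if n_datasets < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 methods")
    if np.isnan(perf).any():
        raise ValueError("performance matrix contains missing cells")
    methods = tuple(methods) if methods else tuple(f"m{j}" for j in range(k))
    datasets = tuple(datasets) if datasets else tuple(f"d{i}" for i in range(n_datasets))
    signed = -perf if larger_is_better else perf
    ranks = np.vstack([st.rankdata(row) for row in signed])
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n_datasets / (k * (k + 1)) * float(
        np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    df = k - 1
    p = float(st.chi2.sf(chi2, df))
    return RankComparison(methods=methods, datasets=datasets, performance=perf,
                          ranks=ranks, mean_ranks=mean_ranks,
                          friedman_chi2=chi2, df=df, p_value=p)


def nemenyi_posthoc(comparison: RankComparison, alpha: float = 0.05) -> RankComparison:
    """Pairwise Nemenyi test on the mean ranks of a Friedman comparison.

    The standardized mean-rank difference is referred to the studentized
    range distribution (infinite df); the critical difference uses
    q_alpha = studentized-range quantile / sqrt(2).
    """
    k = len(comparison.methods)
    if k < 2:
        raise ValueError("need at least 2 methods")
    n = len(comparison.datasets)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(comparison.mean_ranks[i] - comparison.mean_ranks[j]) / se
            p = float(st.studentized_range.sf(q * math.sqrt(2.0), k, np.inf))
            pmat[i, j] = pmat[j, i] = min(1.0, p)
    q_alpha = float(st.studentized_range.ppf(1.0 - alpha, k, np.inf)) / math.sqrt(2.0)
    comparison.nemenyi_p = pmat
    comparison.critical_difference = q_alpha * se
    comparison.alpha = alpha
    return comparison


def compare_classifiers(performance, methods=None, datasets=None,
                        alpha: float = 0.05) -> RankComparison:
    """Friedman omnibus followed by the Nemenyi post-hoc in one call."""
    return nemenyi_posthoc(friedman_test(performance, methods, datasets),
                           alpha=alpha)


@dataclass(frozen=True)
class GroupSimilarityComparison:
    """Average scaled similarity of positive, negative and random pairs."""

    group_means: dict
    group_values: dict
    kruskal_statistic: float
    p_value: float


def group_similarity_comparison(features: pd.DataFrame, net: DrugNetwork,
                                feature_columns: list[str], n_random: int = 1000,
                                seed: int = 0,
                                featurizer=None) -> GroupSimilarityComparison:
    """Compare per-pair average z-scaled similarity between positive-labeled,
    negative-labeled, and freshly drawn random pairs.

    Random pairs are sampled uniformly from the non-edge space and scored
    with the same scaling (fit on the labeled rows).  ``featurizer`` maps a
    bare pair table to a table carrying all of ``feature_columns``; when
    omitted, a topological featurizer on ``net`` is used and any semantic
    columns of the random group are 0.  Significance by the Kruskal-Wallis
    rank sum test over the three groups.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    labels = features["label"].to_numpy(dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both labeled groups must be nonempty")
    mat = features[feature_columns].to_numpy(dtype=float)
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale_safe = np.where(scale == 0, 1.0, scale)

    def avg_scaled(rows: np.ndarray) -> np.ndarray:
        z = (rows - mean) / scale_safe
        z[:, scale == 0] = 0.0
        return z.mean(axis=1)

    rng = np.random.default_rng(seed)
    random_pairs = _sample_negatives(net, n_random, rng)
    rand_df = pd.DataFrame(random_pairs, columns=["drug_id_1", "drug_id_2"])
    rand_df["label"] = 0
    if featurizer is None:
        from .topology import TopologicalPairFeaturizer

        featurizer = TopologicalPairFeaturizer().fit(net).transform
    rand_feat = featurizer(rand_df)
    rand_mat = np.zeros((n_random, len(feature_columns)))
    for j, col in enumerate(feature_columns):
        if col in rand_feat.columns:
            rand_mat[:, j] = rand_feat[col].to_numpy(dtype=float)
    values = {
        "positive": avg_scaled(mat[labels == 1]),
        "negative": avg_scaled(mat[labels == 0]),
        "random": avg_scaled(rand_mat),
    }
    stat, p = st.kruskal(*values.values())
    return GroupSimilarityComparison(
        group_means={k: float(v.mean()) for k, v in values.items()},
        group_values=values,
        kruskal_statistic=float(stat),
        p_value=float(p),
    )


@dataclass(frozen=True)
class FeatureDendrogram:
    """Ward/Euclidean agglomerative clustering of feature columns."""

    feature_names: tuple[str, ...]
    linkage: np.ndarray
    metric: str = "euclidean"
    method: str = "ward"

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels for the feature columns."""
        flat = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.feature_names, (int(c) for c in flat)))


def feature_dendrogram(features: pd.DataFrame,
                       feature_columns: list[str] | None = None) -> FeatureDendrogram:
    """Hierarchically cluster feature columns (Ward linkage, Euclidean).

    Columns are z-scaled first (constant columns become all-zero vectors);
    each feature is a point whose coordinates are its values over the pairs.
    """
    cols = feature_columns or [c for c in features.columns
                               if c not in ("drug_id_1", "drug_id_2", "label")]
    if len(cols) < 2:
        raise ValueError("need at least 2 feature columns")
    mat = features[cols].to_numpy(dtype=float)
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale_safe = np.where(scale == 0, 1.0, scale)
    z = (mat - mean) / scale_safe
    z[:, scale == 0] = 0.0
    linkage = sch.linkage(z.T, method="ward", metric="euclidean")
    return FeatureDendrogram(feature_names=tuple(cols), linkage=linkage)
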