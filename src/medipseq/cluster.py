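"""Sample clustering on DMRs: Ward/Pearson trees, similarity matrices and
prediction-strength estimation of cluster-number stability.

Distances between samples are ``1 - Pearson r`` of their feature profiles;
Ward linkage is applied to that precomputed distance matrix through the
Lance-Williams update (the classical Ward criterion assumes Euclidean
distances — combining it with correlation distance follows the practice of
methylome studies, so the update-formula route is used as-is). Cluster-number
stability is assessed with the prediction-strength statistic: the data are
split into train/test halves, both are clustered, test samples are also
assigned to their nearest train centroid, and ps(k) is the worst-case
proportion of test-cluster pairs that the train clustering keeps together.
Values above ~0.8 indicate well-separated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dmr import DmrResults


def select_cluster_features(dmr_table: pd.DataFrame, p_select: float = 0.001) -> pd.Index:
    """Features with uncorrected p below the selection threshold.

    The cluster analysis runs on the strongly discriminating features only
    (default p < 0.001); an empty selection is an error suggesting a looser
    threshold rather than a silent empty clustering.
    """
    if isinstance(dmr_table, DmrResults):
        dmr_table = dmr_table.table
    sel = dmr_table.index[dmr_table["p"] < p_select]
    if len(sel) == 0:
        raise ValueError(
            f"no features with p < {p_select}; loosen the selection threshold"
        )
    return sel


def correlation_distance(values: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between sample columns; errors on zero-variance samples."""
    sds = values.std(axis=0, ddof=1)
    flat = sds.index[sds <= 1e-12].tolist()
    if flat:
        raise ValueError(f"zero-variance sample profile(s): {flat}")
    corr = values.corr(method="pearson")
    return 1.0 - corr


def ward_cluster(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward linkage on correlation distance between sample columns.

    Returns the scipy linkage matrix and the dendrogram leaf order (sample
    ids). Requires >= 3 samples and >= 2 features; ties are broken
    deterministically by sample order.
    """
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 features to cluster")
    dist = correlation_distance(values)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    order = hierarchy.leaves_list(Z)
    return Z, [values.columns[i] for i in order]


def pairwise_similarity(values: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson matrix ordered by the dendrogram leaf order."""
    _, order = ward_cluster(values)
    return values.corr(method="pearson").loc[order, order]


def cut_clusters(values: pd.DataFrame, k: int) -> pd.Series:
    """Cluster labels (1..k) from the Ward/Pearson tree cut at k."""
    Z, _ = ward_cluster(values)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=values.columns)


def _centroid_assign(test: pd.DataFrame, train: pd.DataFrame, train_labels: pd.Series) -> pd.Series:
    """Assign test samples to the nearest train-cluster centroid in
    correlation distance (centroid = mean profile of the cluster)."""
    out = {}
    cents = {c: train.loc[:, train_labels.index[train_labels == c]].mean(axis=1) for c in sorted(train_labels.unique())}
    for s in test.columns:
        v = test[s]
        best, best_d = None, np.inf
        for c, cent in cents.items():
            sd = cent.std(ddof=1)
            d = 1.0 if sd == 0 or v.std(ddof=1) == 0 else 1.0 - float(np.corrcoef(v, cent)[0, 1])
            if d < best_d:
                best, best_d = c, d
        out[s] = best
    return pd.Series(out)


@dataclass
class PredictionStrength:
    """ps(k) curve with per-fold values and standard errors."""

    table: pd.DataFrame  # k, ps_mean, ps_se
    folds: pd.DataFrame  # k x fold values
    singleton_events: int

    def ps(self, k: int) -> float:
        return float(self.table.set_index("k").loc[k, "ps_mean"])


def prediction_strength(
    values: pd.DataFrame, k_max: int, n_folds: int = 5, seed: int = 0
) -> PredictionStrength:
    """Cross-validated prediction strength for k = 1..k_max.

    For each fold the samples are split into train/test halves; both halves
    are Ward/Pearson-clustered into k groups and the test samples are also
    assigned to their nearest train centroid. ps(k) is the minimum, over
    test clusters, of the proportion of same-cluster test pairs that the
    train-centroid assignment keeps together; ps(1) = 1 by definition.
    Singleton test clusters contribute a proportion of 1 (no pairs) and are
    counted in ``singleton_events``.
    """
    n = values.shape[1]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError(f"need >= {2 * k_max} samples for k_max = {k_max}")
    rng = np.random.default_rng(seed)
    fold_vals = np.ones((k_max, n_folds))
    singletons = 0
    for fold in range(n_folds):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[: n // 2], perm[n // 2 :]
        test = values.iloc[:, np.sort(test_idx)]
        train = values.iloc[:, np.sort(train_idx)]
        for k in range(2, k_max + 1):
            test_labels = cut_clusters(test, k)
            train_labels = cut_clusters(train, k)
            assigned = _centroid_assign(test, train, train_labels)
            worst = 1.0
            for c in sorted(test_labels.unique()):
                members = test_labels.index[test_labels == c]
                if len(members) < 2:
                    singletons += 1
                    continue
                pairs = co = 0
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        pairs += 1
                        if assigned[members[i]] == assigned[members[j]]:
                            co += 1
                worst = min(worst, co / pairs)
            fold_vals[k - 1, fold] = worst
    table = pd.DataFrame(
        {
            "k": np.arange(1, k_max + 1),
            "ps_mean": fold_vals.mean(axis=1),
            "ps_se": fold_vals.std(axis=1, ddof=1) / np.sqrt(n_folds),
        }
    )
    folds = pd.DataFrame(fold_vals, index=pd.Index(range(1, k_max + 1), name="k"))
    return PredictionStrength(table, folds, singletons)


@dataclass
class ClusterReport:
    """Full clustering output for one feature selection."""

    selected: pd.Index
    linkage: np.ndarray
    leaf_order: list[str]
    similarity: pd.DataFrame
    strength: PredictionStrength | None

    def summary(self) -> str:
        lines = [
            f"Cluster analysis on {len(self.selected)} selected features",
            f"  leaf order: {', '.join(self.leaf_order)}",
        ]
        if self.strength is not None:
            best = self.strength.table.iloc[1:].sort_values("ps_mean").iloc[-1]
            lines.append(
                f"  prediction strength: best k>1 is k={int(best.k)} "
                f"(ps = {best.ps_mean:.3f} +/- {best.ps_se:.3f})"
            )
        return "\n".join(lines)


def cluster_report(
    matrix_values: pd.DataFrame,
    dmr_table: pd.DataFrame,
    p_select: float = 0.001,
    k_max: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> ClusterReport:
    """Select features, cluster samples and estimate cluster stability."""
    selected = select_cluster_features(dmr_table, p_select)
    sub = matrix_values.loc[matrix_values.index.intersection(selected)]
    Z, order = ward_cluster(sub)
    sim = sub.corr(method="pearson").loc[order, order]
    strength = None
    if k_max is not None and sub.shape[1] >= 2 * k_max:
        strength = prediction_strength(sub, k_max, n_folds, seed)
    return ClusterReport(selected, Z, order, sim, strength)


def write_linkage(Z: np.ndarray, path) -> None:
    """4-column merge table (left, right, height, size) as text."""
    pd.DataFrame(Z, columns=["left", "right", "height", "size"]).to_csv(
        path, sep="\t", index=False
    )
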