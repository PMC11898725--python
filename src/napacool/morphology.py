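"""Morphological classification of cabbage heads.

Heads are clustered on (length circumference, width circumference, weight)
with K-means after z-standardization — the traits mix centimetres and
grams, so unscaled Euclidean distance would be dominated by weight.  The
cluster count is selected by the mean silhouette coefficient, with the SSE
elbow curve kept as a diagnostic, and clusters are relabelled into size
classes 1..k by ascending mean weight.  A greedy allocator then packs one
head of each class per basket so the metabolic heat load is balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

TRAIT_COLUMNS = ["length_circumference_cm", "width_circumference_cm", "weight_g"]


def _features(records) -> np.ndarray:
    """Feature matrix from a record table (or pass an array through)."""
    if isinstance(records, pd.DataFrame):
        return records[TRAIT_COLUMNS].to_numpy(dtype=float)
    x = np.asarray(records, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (x - mean) / scale, mean, scale


@dataclass
class ClusterModel:
    """Fitted K-means state in standardized trait space.

    ``labels`` are 1-based cluster indices; ``class_order`` maps each
    cluster to a size class 1..k by ascending (destandardized) centroid
    weight, so class 1 is always the smallest heads.
    """

    k: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    centroids: np.ndarray  # k x n_features, standardized space
    labels: np.ndarray  # 1..k per record
    sse: float
    class_order: dict = field(default_factory=dict)

    @property
    def centroids_original(self) -> np.ndarray:
        return self.centroids * self.scaler_scale + self.scaler_mean

    @property
    def class_labels(self) -> np.ndarray:
        """Size-class label (1..k, ascending weight) per record."""
        return np.array([self.class_order[c] for c in self.labels])


def kmeans_fit(records, k: int, seed: int = 0, n_restarts: int = 10) -> ClusterModel:
    """Best-of-``n_restarts`` K-means (k-means++ init) on z-scored traits."""
    x = _features(records)
    if len(x) == 0:
        raise ValueError("empty input")
    z, mean, scale = _standardize(x)
    if len(np.unique(z, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points for k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed, tol=1e-8)
    km.fit(z)
    labels = km.labels_ + 1
    # Rank clusters into size classes by mean weight (last feature column).
    weight_col = z.shape[1] - 1
    cent_orig = km.cluster_centers_ * scale + mean
    order = np.argsort(cent_orig[:, weight_col])
    class_order = {int(cluster + 1): int(rank + 1) for rank, cluster in enumerate(order)}
    return ClusterModel(
        k=k,
        scaler_mean=mean,
        scaler_scale=scale,
        centroids=km.cluster_centers_,
        labels=labels,
        sse=float(km.inertia_),
        class_order=class_order,
    )


def sse_curve(records, k_range, seed: int = 0, n_restarts: int = 10) -> list[tuple[int, float]]:
    """(k, SSE) pairs over ``k_range``; SSE is nonincreasing in k."""
    k_range = list(k_range)
    if not k_range or any(b <= a for a, b in zip(k_range, k_range[1:])):
        raise ValueError("k_range must be nonempty and increasing")
    return [(k, kmeans_fit(records, k, seed=seed, n_restarts=n_restarts).sse) for k in k_range]


def silhouette_mean(records, labels) -> float:
    """Mean silhouette coefficient of a labelling, on z-scored traits.

    Per record, ``(b - a)/max(a, b)`` with ``a`` the mean distance to the
    record's own cluster (excluding itself) and ``b`` the smallest mean
    distance to any other cluster; singleton clusters contribute 0.
    """
    x = _features(records)
    labels = np.asarray(labels)
    if len(x) < 2:
        raise ValueError("need at least 2 records")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    z, _, _ = _standardize(x)
    return float(np.mean(silhouette_samples(z, labels)))


@dataclass
class KSelection:
    """Outcome of cluster-count selection."""

    k_opt: int
    silhouettes: dict  # k -> mean silhouette
    sse: list  # (k, SSE) pairs
    knee: int | None  # elbow of the SSE curve (max second difference)


def select_k(records, k_range=(2, 3, 4, 5), seed: int = 0, n_restarts: int = 10) -> KSelection:
    """Choose the cluster count maximizing the mean silhouette.

    The SSE elbow (largest second difference of the SSE curve) is reported
    as a diagnostic only; the silhouette decides.
    """
    k_range = sorted(set(k_range))
    sil = {}
    for k in k_range:
        model = kmeans_fit(records, k, seed=seed, n_restarts=n_restarts)
        sil[k] = silhouette_mean(records, model.labels)
    curve = sse_curve(records, k_range, seed=seed, n_restarts=n_restarts)
    knee = None
    if len(curve) >= 3:
        sses = [s for _, s in curve]
        second_diff = [sses[i - 1] - 2 * sses[i] + sses[i + 1] for i in range(1, len(sses) - 1)]
        knee = curve[1 + int(np.argmax(second_diff))][0]
    k_opt = max(sil, key=sil.get)
    return KSelection(k_opt=k_opt, silhouettes=sil, sse=curve, knee=knee)


def allocate_baskets(model: ClusterModel, records) -> dict:
    """Heat-balanced basket allocation: one head of each size class per
    basket, pairing light class-1 heads with heavy class-3 heads.

    Each class is sorted by weight; class 1 ascending is paired with class
    3 descending (class 2 ascending), which flattens the per-basket total
    weight and hence the respiration heat load.
    """
    if isinstance(records, pd.DataFrame):
        ids = records["id"].to_numpy() if "id" in records else np.arange(len(records))
        weights = records["weight_g"].to_numpy(dtype=float)
    else:
        x = _features(records)
        ids = np.arange(len(x))
        weights = x[:, -1]
    classes = model.class_labels
    per_class = {c: np.nonzero(classes == c)[0] for c in np.unique(classes)}
    counts = {c: len(ix) for c, ix in per_class.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"class counts must be equal, got {counts}")
    n_baskets = next(iter(counts.values()))

    ordered = {}
    for c, ix in per_class.items():
        by_weight = ix[np.argsort(weights[ix])]
        ordered[c] = by_weight[::-1] if c == max(per_class) else by_weight
    baskets = {}
    for b in range(n_baskets):
        baskets[b] = [ids[ordered[c][b]] for c in sorted(ordered)]
    return baskets


@dataclass
class ClusteringResults:
    """Results object for a fitted morphology classification."""

    model: ClusterModel
    records: pd.DataFrame = field(repr=False)
    silhouette: float = 0.0

    @property
    def class_labels(self) -> np.ndarray:
        return self.model.class_labels

    def class_summary(self) -> pd.DataFrame:
        df = self.records.copy()
        df["class"] = self.class_labels
        return df.groupby("class")[TRAIT_COLUMNS].agg(["mean", "std", "count"])

    def summary(self) -> str:
        lines = [
            "Morphology K-means classification",
            "---------------------------------",
            f"records:         {len(self.records)}",
            f"clusters (k):    {self.model.k}",
            f"SSE:             {self.model.sse:.3f}",
            f"mean silhouette: {self.silhouette:.3f}",
            "",
            "per-class trait means (ascending weight):",
        ]
        df = self.records.copy()
        df["class"] = self.class_labels
        means = df.groupby("class")[TRAIT_COLUMNS].mean()
        counts = df.groupby("class").size()
        for c, row in means.iterrows():
            lines.append(
                f"  class {c} (n={counts[c]}): length {row[TRAIT_COLUMNS[0]]:.2f} cm, "
                f"width {row[TRAIT_COLUMNS[1]]:.2f} cm, weight {row[TRAIT_COLUMNS[2]]:.2f} g"
            )
        return "\n".join(lines)


class MorphologyClassifier:
    """Model object for head classification from a morphology table."""

    def __init__(self, records: pd.DataFrame):
        self.records = records

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MorphologyClassifier":
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "MorphologyClassifier":
        return cls(pd.read_csv(path))

    def fit(self, k: int = 3, seed: int = 0, n_restarts: int = 10) -> ClusteringResults:
        model = kmeans_fit(self.records, k, seed=seed, n_restarts=n_restarts)
        sil = silhouette_mean(self.records, model.labels) if k >= 2 else float("nan")
        return ClusteringResults(model=model, records=self.records, silhouette=sil)

    def select_k(self, k_range=(2, 3, 4, 5), seed: int = 0, n_restarts: int = 10) -> KSelection:
        return select_k(self.records, k_range=k_range, seed=seed, n_restarts=n_restarts)
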