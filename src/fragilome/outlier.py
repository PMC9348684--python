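"""Clustering-based outlier detection over genome feature matrices.

Genomes are represented either by the 64 components of their triplet
distribution or by the 3 quadratic coefficients of their entropy
degradation trajectory.  Columns are standardized, genomes are clustered
agglomeratively on Euclidean distances (complete linkage, or the classical
Ward update applied to raw distances — the ``ward.D`` convention of R's
``hclust`` — with the squared-distance variant exposed as ``ward2``),
cluster centroids are embedded in 2-D by classical (Torgerson) MDS, and
small, well-separated clusters are flagged as outlier candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "Embedding2D",
    "OutlierReport",
    "standardize",
    "hierarchical_cluster",
    "choose_k",
    "choose_k_scores",
    "embed_centroids",
    "cross_tabulate",
    "variance_explained",
    "flag_outliers",
]

LINKAGES = ("complete", "ward", "ward2")


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = genomes, columns = named real-valued features."""

    ids: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("values shape does not match ids x columns")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate genome ids in feature matrix")
        if self.standardized:
            v = self.values
            keep = v.std(axis=0) > 0
            if keep.any():
                m = np.abs(v[:, keep].mean(axis=0)).max()
                if m > 1e-9:
                    raise ValueError("standardized matrix has non-zero column means")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardized: bool = False) -> "FeatureMatrix":
        return cls(
            ids=tuple(str(i) for i in frame.index),
            columns=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            standardized=standardized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.columns))


@dataclass(frozen=True)
class ClusterModel:
    """Result of cutting an agglomerative tree into k clusters.

    ``labels`` are 1-based cluster numbers aligned with ``ids``, renumbered
    by dendrogram leaf order (cluster 1 at the bottom of the tree).
    ``merge_tree`` is the scipy-format linkage matrix.
    """

    ids: tuple[str, ...]
    labels: np.ndarray = field(repr=False)
    k: int
    linkage: str
    merge_tree: np.ndarray = field(repr=False)
    centroids: np.ndarray = field(repr=False)  # (k, p) feature means
    features: FeatureMatrix = field(repr=False)

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        if len(uniq) != self.k or uniq.min() != 1 or uniq.max() != self.k:
            raise ValueError("labels must take exactly the values 1..k")
        if int(np.bincount(self.labels)[1:].sum()) != len(self.ids):
            raise ValueError("cluster sizes must sum to the genome count")

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes indexed 0..k-1 for clusters 1..k."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, cluster: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == cluster]

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.ids), name="cluster")


@dataclass(frozen=True)
class Embedding2D:
    """2-D classical MDS coordinates of cluster centroids."""

    coords: np.ndarray = field(repr=False)  # (k, 2)
    stress: float = 0.0

    def __post_init__(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")


@dataclass(frozen=True)
class OutlierReport:
    """Flagged genomes with the per-cluster rule that triggered them."""

    flagged_ids: tuple[str, ...]
    flagged_clusters: tuple[int, ...]
    rationale: Mapping[int, str]


def standardize(features: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores (sample standard deviation, ddof=1).

    Constant columns are mapped to zeros with a warning.  Idempotent.
    """
    if len(features.ids) < 2:
        raise ValueError("standardization needs at least 2 rows")
    v = features.values.astype(float)
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature column(s) mapped to zeros",
            stacklevel=2,
        )
    sd = np.where(const, 1.0, sd)
    z = (v - mean) / sd
    z[:, const] = 0.0
    return FeatureMatrix(
        ids=features.ids, columns=features.columns, values=z, standardized=True
    )


def _ward_d_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward's Lance-Williams update applied to *raw* Euclidean distances.

    This replicates the ``ward.D`` option of R's hclust, which feeds
    unsquared dissimilarities into the Ward recurrence (the orthodox
    variant on squared distances is scipy's ``ward`` / R's ``ward.D2``).
    Greedy global-minimum merges; returns a scipy-format linkage matrix.
    """
    n = dist.shape[0]
    D = dist.copy().astype(float)
    np.fill_diagonal(D, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    # map row index in D -> current cluster id (scipy numbering)
    cluster_id = list(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        i, j = active[ai], active[aj]
        if i > j:
            i, j = j, i
        h = D[i, j]
        ci, cj = cluster_id[i], cluster_id[j]
        ni, nj = sizes[i], sizes[j]
        Z[step] = [min(ci, cj), max(ci, cj), h, ni + nj]
        # Lance-Williams Ward update against every other active cluster
        for m in active:
            if m in (i, j):
                continue
            nm = sizes[m]
            denom = ni + nj + nm
            new = ((ni + nm) * D[i, m] + (nj + nm) * D[j, m] - nm * h) / denom
            D[i, m] = D[m, i] = new
        sizes[i] = ni + nj
        cluster_id[i] = next_id
        next_id += 1
        active.remove(j)
        D[j, :] = D[:, j] = np.inf
    return Z


def compute_linkage(features: FeatureMatrix, method: str = "complete") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) on Euclidean distances."""
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    v = features.values
    if np.isnan(v).any():
        raise ValueError("feature matrix contains NaN")
    if method == "complete":
        return linkage(v, method="complete", metric="euclidean")
    if method == "ward2":
        return linkage(v, method="ward", metric="euclidean")
    return _ward_d_linkage(squareform(pdist(v)))


def _renumber_by_leaf_order(labels0: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Renumber raw cut labels so cluster 1 sits at the bottom of the tree."""
    order = leaves_list(Z)
    first_pos: dict[int, int] = {}
    for pos, leaf in enumerate(order):
        lab = int(labels0[leaf])
        first_pos.setdefault(lab, pos)
    ranked = sorted(first_pos, key=first_pos.get)
    remap = {old: new for new, old in enumerate(ranked, start=1)}
    return np.array([remap[int(l)] for l in labels0], dtype=int)


def hierarchical_cluster(
    features: FeatureMatrix, linkage_method: str = "complete", k: int = 2
) -> ClusterModel:
    """Cluster genomes agglomeratively and cut the tree into k clusters."""
    n = len(features.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    Z = compute_linkage(features, linkage_method)
    labels0 = cut_tree(Z, n_clusters=k).ravel()
    labels = _renumber_by_leaf_order(labels0, Z)
    centroids = np.vstack(
        [features.values[labels == c].mean(axis=0) for c in range(1, k + 1)]
    )
    return ClusterModel(
        ids=features.ids,
        labels=labels,
        k=k,
        linkage=linkage_method,
        merge_tree=Z,
        centroids=centroids,
        features=features,
    )


def choose_k_scores(
    features: FeatureMatrix, merge_tree: np.ndarray, k_max: int = 20
) -> pd.DataFrame:
    """Calinski-Harabasz score for every cut k in 2..k_max, plus merge heights."""
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    n = len(features.ids)
    k_max = min(k_max, n - 1)
    rows = []
    heights = merge_tree[:, 2]
    for k in range(2, k_max + 1):
        labels = cut_tree(merge_tree, n_clusters=k).ravel()
        ch = calinski_harabasz_score(features.values, labels)
        # height of the merge undone when moving from k-1 to k clusters
        drop = heights[n - k] - (heights[n - k - 1] if n - k - 1 >= 0 else 0.0)
        rows.append({"k": k, "calinski_harabasz": ch, "height_drop": drop})
    return pd.DataFrame(rows).set_index("k")


def choose_k(features: FeatureMatrix, merge_tree: np.ndarray, k_max: int = 20) -> int:
    """Smallest k in 2..k_max at a local maximum of the Calinski-Harabasz index.

    A documented stand-in for generic fit/complexity heuristics: the index
    measures between/within dispersion (fit), and taking the *first* local
    maximum rather than the global one prefers parsimonious solutions —
    once splitting further stops improving the index, stop.  Falls back to
    the global argmax if the index climbs monotonically.  Deterministic
    for a given tree; the per-k score table (including an elbow-style
    merge-height profile) is available from :func:`choose_k_scores`.
    """
    scores = choose_k_scores(features, merge_tree, k_max)
    ch = scores["calinski_harabasz"]
    ks = list(ch.index)
    for i, k in enumerate(ks):
        left_ok = i == 0 or ch.iloc[i] >= ch.iloc[i - 1]
        right_ok = i == len(ks) - 1 or ch.iloc[i] >= ch.iloc[i + 1]
        if left_ok and right_ok:
            return int(k)
    return int(ch.idxmax())


def embed_centroids(model: ClusterModel) -> Embedding2D:
    """Classical (Torgerson) MDS of the centroid distance matrix into 2-D.

    Double-centers the squared Euclidean distance matrix, takes the top two
    eigenpairs, and scales eigenvectors by sqrt(eigenvalue); non-positive
    eigenvalues contribute a zero coordinate (collinear centroids embed on
    a line).  ``stress`` is the relative rms error between embedded and
    input distances.
    """
    if model.k < 3:
        raise ValueError("need at least 3 centroids to embed")
    D = squareform(pdist(model.centroids))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[idx], 0.0, None)
    coords = eigvec[:, idx] * np.sqrt(lam)
    Dhat = squareform(pdist(coords))
    denom = float((D**2).sum())
    stress = float(np.sqrt(((D - Dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
    return Embedding2D(coords=coords, stress=stress)


def _labels_series(x: "ClusterModel | pd.Series | Mapping[str, int]") -> pd.Series:
    if isinstance(x, ClusterModel):
        return x.labels_series()
    if isinstance(x, pd.Series):
        return x
    return pd.Series(dict(x))


def cross_tabulate(
    labels_a: "ClusterModel | pd.Series | Mapping[str, int]",
    labels_b: "ClusterModel | pd.Series | Mapping[str, int]",
) -> pd.DataFrame:
    """Contingency table of two clusterings of the same genomes.

    Rows are clusters of ``labels_a``, columns of ``labels_b``; includes
    row/column sums and the grand sum (margins labelled ``Sum``).
    """
    a, b = _labels_series(labels_a), _labels_series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("clusterings cover different genome sets")
    b = b.reindex(a.index)
    return pd.crosstab(a, b, margins=True, margins_name="Sum")


def variance_explained(
    features: FeatureMatrix,
    labels: "ClusterModel | pd.Series | Mapping[str, int]",
) -> pd.Series:
    """Percent of each column's variation explained by cluster membership.

    Per column: 100 x between-cluster sum of squares / total sum of
    squares (one-way ANOVA R-squared).  A single cluster yields 0 by
    convention; k = n singletons yield 100.
    """
    lab = _labels_series(labels).reindex(list(features.ids))
    if lab.isna().any():
        raise ValueError("labels do not cover the feature matrix ids")
    v = features.values
    out = []
    groups = lab.to_numpy()
    uniq = np.unique(groups)
    for j, col in enumerate(features.columns):
        y = v[:, j]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0 or len(uniq) == 1:
            out.append(100.0 if ss_tot == 0.0 and len(uniq) > 1 else 0.0)
            continue
        ss_between = 0.0
        for g in uniq:
            yg = y[groups == g]
            ss_between += len(yg) * (yg.mean() - y.mean()) ** 2
        out.append(100.0 * ss_between / ss_tot)
    return pd.Series(out, index=list(features.columns), name="pct_variance_explained")


def flag_outliers(
    model: ClusterModel,
    max_size_fraction: float = 0.01,
    min_centroid_separation: float = 2.0,
) -> OutlierReport:
    """Flag small, strongly separated clusters as outlier candidates.

    A cluster is flagged when its size is at most ``max_size_fraction`` of
    the genome count AND its centroid's distance to the nearest
    *non-candidate* centroid is at least ``min_centroid_separation`` times
    the median inter-centroid distance.  The flag set is monotone
    nondecreasing in ``max_size_fraction``.  Defaults suit databases of
    tens of thousands of genomes; for small databases pass a larger size
    fraction (the pipeline layer does).
    """
    n = len(model.ids)
    if model.k < 2:
        return OutlierReport(flagged_ids=(), flagged_clusters=(), rationale={})
    sizes = model.sizes
    small = sizes <= max_size_fraction * n
    if not small.any() or small.all():
        # nothing small, or no bulk cluster to measure separation from
        return OutlierReport(flagged_ids=(), flagged_clusters=(), rationale={})
    D = squareform(pdist(model.centroids))
    median_dist = float(np.median(D[np.triu_indices_from(D, k=1)]))
    flagged: list[int] = []
    rationale: dict[int, str] = {}
    bulk = (~small).nonzero()[0]
    for c in small.nonzero()[0]:
        nearest = float(D[c, bulk].min())
        if median_dist == 0.0 or nearest >= min_centroid_separation * median_dist:
            cluster = c + 1
            flagged.append(cluster)
            rationale[cluster] = (
                f"size {sizes[c]} <= {max_size_fraction:.3g} x {n}; "
                f"nearest bulk centroid at {nearest:.3g} >= "
                f"{min_centroid_separation:.3g} x median {median_dist:.3g}"
            )
    ids = tuple(
        i for i, l in zip(model.ids, model.labels) if l in set(flagged)
    )
    return OutlierReport(
        flagged_ids=ids, flagged_clusters=tuple(flagged), rationale=rationale
    )
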