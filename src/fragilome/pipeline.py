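"""End-to-end outlier-detection pipelines.

Two routes from a genome collection to flagged outliers:

* **entropy degradation** — degrade every genome over the standard
  checkpoints, fit a quadratic to its triplet-entropy trajectory,
  standardize the three coefficients, cluster (Ward on raw distances),
  and flag small well-separated clusters;
* **triplet distribution** — standardize the 64 triplet-distribution
  components and cluster with complete linkage; the first split of the
  dendrogram is the coarsest outlier/bulk partition.

Pipeline flagging defaults are scaled for databases of a few hundred
genomes (size fraction 0.05, separation 1.0 x the median inter-centroid
distance); see :func:`fragilome.outlier.flag_outliers` for the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .degrade import MutationConfig
from .ngram import tuple_distribution, words
from .outlier import (
    ClusterModel,
    FeatureMatrix,
    OutlierReport,
    choose_k,
    flag_outliers,
    hierarchical_cluster,
    standardize,
)
from .seqio import Genome
from .trajectory import (
    DEFAULT_CHECKPOINTS,
    entropy_trajectory,
    fit_quadratic,
)

__all__ = [
    "entropy_feature_table",
    "triplet_feature_matrix",
    "detect_entropy_outliers",
    "detect_triplet_outliers",
    "first_split",
    "EntropyOutlierResult",
    "TripletOutlierResult",
]

_SEED_CAP = 2**31 - 1


def entropy_feature_table(
    genomes: Sequence[Genome],
    config: MutationConfig | None = None,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    n: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Quadratic entropy-degradation features for every genome.

    Each genome gets its own degradation RNG stream (seeded from ``seed``
    in collection order).  Returns a frame indexed by genome id with
    columns ``c0, c1, c2, r2``.  ``config`` defaults to the SNP-only
    measurement probe (:meth:`MutationConfig.probe`).
    """
    config = config or MutationConfig.probe()
    master = np.random.default_rng(seed)
    rows = {}
    for g in genomes:
        s = int(master.integers(_SEED_CAP))
        traj = entropy_trajectory(
            g, config.with_seed(s), checkpoints=checkpoints, n=n
        )
        q = fit_quadratic(traj)
        rows[g.id] = {"c0": q.c0, "c1": q.c1, "c2": q.c2, "r2": q.r2}
    return pd.DataFrame.from_dict(rows, orient="index")


def triplet_feature_matrix(genomes: Sequence[Genome], n: int = 3) -> FeatureMatrix:
    """The 4^n tuple-distribution components of every genome as features."""
    values = np.vstack([tuple_distribution(g, n).probs for g in genomes])
    return FeatureMatrix(
        ids=tuple(g.id for g in genomes),
        columns=tuple(words(n)),
        values=values,
    )


@dataclass(frozen=True)
class EntropyOutlierResult:
    features: pd.DataFrame = field(repr=False)
    model: ClusterModel = field(repr=False)
    report: OutlierReport

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return self.report.flagged_ids


@dataclass(frozen=True)
class TripletOutlierResult:
    model: ClusterModel = field(repr=False)
    report: OutlierReport
    first_split_ids: tuple[str, ...]

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return self.report.flagged_ids


def detect_entropy_outliers(
    genomes: Sequence[Genome],
    config: MutationConfig | None = None,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    n: int = 3,
    seed: int = 0,
    linkage: str = "ward",
    k: int | None = None,
    k_max: int = 20,
    max_size_fraction: float = 0.05,
    min_centroid_separation: float = 1.0,
) -> EntropyOutlierResult:
    """Entropy-degradation outlier pipeline.

    Degrades every genome, compresses triplet-entropy trajectories to
    quadratic coefficients, standardizes them, clusters with the requested
    linkage (``k`` chosen by the Calinski-Harabasz scan when not given)
    and flags small, separated clusters.
    """
    feats = entropy_feature_table(genomes, config, checkpoints, n=n, seed=seed)
    fm = standardize(FeatureMatrix.from_frame(feats[["c0", "c1", "c2"]]))
    model = _cluster(fm, linkage, k, k_max)
    report = flag_outliers(model, max_size_fraction, min_centroid_separation)
    return EntropyOutlierResult(features=feats, model=model, report=report)


def detect_triplet_outliers(
    genomes: Sequence[Genome],
    n: int = 3,
    linkage: str = "complete",
    k: int | None = None,
    k_max: int = 20,
    max_size_fraction: float = 0.05,
    min_centroid_separation: float = 1.0,
) -> TripletOutlierResult:
    """Tuple-distribution outlier pipeline (no degradation required)."""
    fm = standardize(triplet_feature_matrix(genomes, n=n))
    model = _cluster(fm, linkage, k, k_max)
    report = flag_outliers(model, max_size_fraction, min_centroid_separation)
    return TripletOutlierResult(
        model=model, report=report, first_split_ids=first_split(model)
    )


def _cluster(
    fm: FeatureMatrix, linkage: str, k: int | None, k_max: int
) -> ClusterModel:
    from .outlier import compute_linkage

    Z = compute_linkage(fm, linkage)
    if k is None:
        k = choose_k(fm, Z, k_max=k_max)
    return hierarchical_cluster(fm, linkage, k)


def first_split(model: ClusterModel) -> tuple[str, ...]:
    """Members of the smaller branch of the dendrogram's first split."""
    from scipy.cluster.hierarchy import cut_tree

    labels2 = cut_tree(model.merge_tree, n_clusters=2).ravel()
    sizes = np.bincount(labels2)
    minority = int(np.argmin(sizes))
    return tuple(i for i, l in zip(model.ids, labels2) if l == minority)
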