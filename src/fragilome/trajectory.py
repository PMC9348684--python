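"""Degradation trajectories and their quadratic summaries.

A trajectory records a metric value at each iteration checkpoint of a
degradation run: either the entropy of the snapshot's n-tuple distribution
(movement toward the universal maximum-entropy endpoint) or the distance of
the snapshot from a fixed origin genome.  Entropy trajectories are
compressed to three least-squares quadratic coefficients plus R-squared;
the coefficients are the features the outlier layer clusters on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import metrics
from .alphabet import decode
from .degrade import MutationConfig, iter_degraded
from .metrics import hamming, hellinger, levenshtein
from .ngram import tuple_distribution
from .seqio import Genome

__all__ = [
    "DegradationTrajectory",
    "QuadraticFeatures",
    "entropy_trajectory",
    "distance_trajectory",
    "fit_quadratic",
]

DEFAULT_CHECKPOINTS = (0, 250, 500, 1000, 2000)


@dataclass(frozen=True)
class DegradationTrajectory:
    """Metric values of one genome at degradation checkpoints."""

    genome_id: str
    metric_name: str
    checkpoints: tuple[int, ...]
    values: tuple[float, ...]
    origin_id: str = "self"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.checkpoints):
            raise ValueError("values and checkpoints differ in length")
        cps = self.checkpoints
        if not cps or cps[0] != 0:
            raise ValueError("checkpoints must start at 0")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("checkpoints must be strictly increasing")


@dataclass(frozen=True)
class QuadraticFeatures:
    """Least-squares quadratic summary of a 5-point trajectory.

    ``value ~ c0 + c1 * k + c2 * k^2`` over iteration counts k, with the
    coefficient of determination ``r2`` (1 by convention when the values
    are constant).
    """

    c0: float
    c1: float
    c2: float
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2])


def entropy_trajectory(
    genome: Genome,
    config: MutationConfig,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    n: int = 3,
    increase: bool = False,
    rng: np.random.Generator | None = None,
) -> DegradationTrajectory:
    """Entropy (bits) of the n-tuple distribution at each checkpoint.

    With ``increase=True`` the checkpoint-0 value is subtracted, giving the
    entropy *increase* curve (movement toward the log2(4^n) maximum).
    """
    vals: list[float] = []
    cap = max(checkpoints)
    for _, codes in iter_degraded(
        genome.codes(), config, checkpoints, rng=rng, max_iterations=max(cap, 2000)
    ):
        vals.append(metrics.entropy(tuple_distribution(codes, n)))
    if increase:
        base = vals[0]
        vals = [v - base for v in vals]
    return DegradationTrajectory(
        genome_id=genome.id,
        metric_name=f"entropy-{n}" + ("-increase" if increase else ""),
        checkpoints=tuple(int(c) for c in checkpoints),
        values=tuple(vals),
        origin_id="max-entropy",
    )


def distance_trajectory(
    genome: Genome,
    origin: Genome,
    config: MutationConfig,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    metric: str = "hamming",
    rng: np.random.Generator | None = None,
) -> DegradationTrajectory:
    """Distance of each degradation snapshot from a fixed origin genome.

    ``metric`` is ``hamming`` (SNP-only configs, since indels make lengths
    diverge and Hamming infinite), ``levenshtein``, or ``hellinger-N`` for
    the Hellinger distance between N-tuple distributions (N in 1..4).  The
    origin may be the genome itself, its undegraded parent, or any fixed
    third genome.
    """
    if metric == "hamming" and not config.snp_only:
        raise ValueError("hamming distance requires a SNP-only config")
    origin_dist = None
    if metric.startswith("hellinger-"):
        n = int(metric.split("-", 1)[1])
        origin_dist = tuple_distribution(origin, n)
    elif metric not in ("hamming", "levenshtein"):
        raise ValueError(f"unknown metric {metric!r}")

    vals: list[float] = []
    cap = max(checkpoints)
    for _, codes in iter_degraded(
        genome.codes(), config, checkpoints, rng=rng, max_iterations=max(cap, 2000)
    ):
        if origin_dist is not None:
            vals.append(hellinger(origin_dist, tuple_distribution(codes, origin_dist.n)))
        elif metric == "hamming":
            vals.append(float(hamming(origin.sequence, decode(codes))))
        else:
            vals.append(float(levenshtein(origin.sequence, decode(codes))))
    return DegradationTrajectory(
        genome_id=genome.id,
        metric_name=metric,
        checkpoints=tuple(int(c) for c in checkpoints),
        values=tuple(vals),
        origin_id=origin.id,
    )


def fit_quadratic(traj: DegradationTrajectory) -> QuadraticFeatures:
    """Ordinary least squares of trajectory values on (1, k, k^2).

    Iteration counts are used raw as the regression abscissa; any
    standardization of the coefficients happens downstream.  R-squared is
    1 - SS_resid / SS_total, with SS_total = 0 (constant values) defining
    R-squared = 1.
    """
    if len(traj.checkpoints) < 3:
        raise ValueError("need at least 3 checkpoints for a quadratic fit")
    k = np.asarray(traj.checkpoints, dtype=float)
    y = np.asarray(traj.values, dtype=float)
    X = np.column_stack([np.ones_like(k), k, k * k])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return QuadraticFeatures(
        c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]),
        r2=float(min(max(r2, 0.0), 1.0)),
    )
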