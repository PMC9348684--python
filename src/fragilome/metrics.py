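"""Degradation and quality metrics.

Distribution-level: Shannon entropy of a tuple distribution (movement
toward the maximal value log 4^n measures degradation from the "endpoint"
side) and Hellinger distance between tuple distributions.  String-level:
Hamming distance (defined infinite between sequences of unequal length,
so it is usable only under SNP-only degradation) and unit-cost Levenshtein
edit distance.  Significance: an empirical null threshold for Hellinger
distance, simulated from a genome's own second-order Markov model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import edlib
import numpy as np

from .ngram import TransitionMatrix, TupleDistribution, transition_matrix, tuple_distribution
from .seqio import Genome

__all__ = [
    "DistanceValue",
    "entropy",
    "hellinger",
    "hamming",
    "levenshtein",
    "null_threshold",
    "HAMMING_INFINITE",
]

#: Distinguished value for Hamming distance between unequal-length strings.
HAMMING_INFINITE = math.inf


@dataclass(frozen=True)
class DistanceValue:
    """A labelled distance, tagged with the origin it was measured from."""

    value: float
    metric_name: str
    origin_id: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("distances are non-negative")


def _probs(dist: TupleDistribution | np.ndarray) -> np.ndarray:
    p = dist.probs if isinstance(dist, TupleDistribution) else np.asarray(dist, float)
    if p.ndim != 1 or (p < 0).any():
        raise ValueError("expected a non-negative probability vector")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"distribution not normalized (sum {p.sum():.6g})")
    return p


def entropy(dist: TupleDistribution | np.ndarray, base: float = 2) -> float:
    """Shannon entropy -sum p log p, zero terms dropped (0 * -inf := 0).

    ``base`` 2 gives bits (default), ``math.e`` gives nats.  Bounded by
    log(4^n) for an n-tuple distribution, attained at uniformity.
    """
    p = _probs(dist)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum() / math.log(base))
    return max(h, 0.0)


def hellinger(p: TupleDistribution | np.ndarray, q: TupleDistribution | np.ndarray) -> float:
    """Hellinger distance sqrt(1 - sum sqrt(p q)) in [0, 1].

    Symmetric, zero iff p = q, one on disjoint supports.  Tuple
    distributions must share the same word length n.
    """
    if isinstance(p, TupleDistribution) and isinstance(q, TupleDistribution):
        if p.n != q.n:
            raise ValueError(f"mismatched tuple lengths: {p.n} vs {q.n}")
    pv, qv = _probs(p), _probs(q)
    if pv.shape != qv.shape:
        raise ValueError("distributions have different dimensions")
    # root-vector form: exact 0 at p = q, no cancellation near identity
    d = float(np.sqrt(0.5 * ((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum()))
    return min(d, 1.0)


def _seq(x: Genome | str) -> str:
    return x.sequence if isinstance(x, Genome) else x


def hamming(a: Genome | str, b: Genome | str) -> float:
    """Mismatch count between equal-length sequences; infinite otherwise."""
    sa, sb = _seq(a), _seq(b)
    if len(sa) != len(sb):
        return HAMMING_INFINITE
    xa = np.frombuffer(sa.encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(sb.encode("ascii"), dtype=np.uint8)
    return int((xa != xb).sum())


def levenshtein(a: Genome | str, b: Genome | str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        return max(len(sa), len(sb))
    res = edlib.align(sa, sb, mode="NW", task="distance")
    return int(res["editDistance"])


def null_threshold(
    genome: Genome,
    n: int,
    alpha: float = 0.01,
    reps: int = 200,
    seed: int = 0,
    null: str = "markov",
) -> float:
    """Simulation-derived Hellinger significance threshold for one genome.

    Simulates ``reps`` sequences of the genome's length from a null model —
    the genome's own second-order Markov model (``null="markov"``, the
    information-preserving default) or iid draws from its base frequencies
    (``null="iid"``) — and returns the (1 - alpha) empirical quantile of
    the Hellinger distances between the genome's n-tuple distribution and
    each simulated one.  A distance above the threshold means the n-tuple
    distribution matches the genome's with probability below alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if reps < 100:
        raise ValueError("reps must be at least 100 for a stable quantile")
    rng = np.random.default_rng(seed)
    ref = tuple_distribution(genome, n)

    if null == "markov":
        tm = transition_matrix(genome)
    elif null == "iid":
        base = tuple_distribution(genome, 1).probs
        rows = np.tile(base, (16, 1))
        pair = np.outer(base, base).ravel()
        tm = TransitionMatrix.from_rows(rows, context_probs=pair)
    else:
        raise ValueError(f"unknown null model {null!r}")

    sims = tm.sample_codes(genome.length, rng, reps=reps)
    dists = np.array(
        [hellinger(ref, tuple_distribution(sims[r], n)) for r in range(reps)]
    )
    thr = float(np.quantile(dists, 1.0 - alpha))
    if thr == 0.0:
        warnings.warn(
            "degenerate genome: null distances all zero, threshold is 0",
            stacklevel=2,
        )
    return thr
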