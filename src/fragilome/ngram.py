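"""Tuple (n-gram) distributions and the second-order Markov model.

The n-gram distribution of a genome G is the probability vector over all
4^n length-n words of contiguous windows of G, counts divided by the
number of counted windows.  Windows containing any non-ACGT character are
excluded from both numerator and denominator (the "tolerate + skip" policy
of :mod:`fragilome.seqio`).  Indexing is lexicographic over A < C < G < T,
so serialized vectors are comparable across runs.

Triplets carry the same information as the pair distribution together with
the 16 x 4 transition matrix giving each base's distribution conditional on
its two predecessors; that pair (the second-order Markov model) is also the
generative null model used elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .alphabet import BASES
from .seqio import Genome

__all__ = [
    "TupleDistribution",
    "TransitionMatrix",
    "tuple_distribution",
    "transition_matrix",
    "words",
]

MAX_N = 4


def words(n: int) -> list[str]:
    """All 4^n length-n words over ACGT in lexicographic order."""
    return ["".join(p) for p in product(BASES, repeat=n)]


@dataclass(frozen=True)
class TupleDistribution:
    """Probability vector over the 4^n length-n words of a genome."""

    n: int
    probs: np.ndarray = field(repr=False)
    window_count: int

    def __post_init__(self) -> None:
        if not 1 <= self.n <= MAX_N:
            raise ValueError(f"n must be in 1..{MAX_N}")
        if self.probs.shape != (4**self.n,):
            raise ValueError(f"probs must have dimension 4^{self.n}")
        if self.window_count > 0 and abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must sum to 1")

    def labels(self) -> list[str]:
        return words(self.n)


@dataclass(frozen=True)
class TransitionMatrix:
    """16 x 4 matrix of base probabilities conditional on the previous pair.

    Rows are the 16 ordered base pairs (lexicographic), columns the four
    successor bases.  Rows for contexts never observed in the source genome
    are NaN and flagged in ``observed`` rather than silently zero-filled.
    ``context_probs`` is the distribution of the prefix pair over counted
    triplet windows, so that P3(b1 b2 b3) = context_probs(b1 b2) *
    probs(b1 b2 -> b3) exactly.
    """

    probs: np.ndarray = field(repr=False)  # (16, 4), NaN on unobserved rows
    observed: np.ndarray = field(repr=False)  # (16,) bool
    context_probs: np.ndarray = field(repr=False)  # (16,)

    def __post_init__(self) -> None:
        if self.probs.shape != (16, 4):
            raise ValueError("transition matrix must be 16 x 4")
        row_sums = np.nansum(self.probs[self.observed], axis=1)
        if self.observed.any() and not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ValueError("observed rows must sum to 1")

    @staticmethod
    def contexts() -> list[str]:
        return words(2)

    @classmethod
    def from_rows(
        cls, probs: np.ndarray, context_probs: np.ndarray | None = None
    ) -> "TransitionMatrix":
        """Build from explicitly normalized rows (all contexts observed)."""
        probs = np.asarray(probs, dtype=float)
        if context_probs is None:
            context_probs = np.full(16, 1.0 / 16)
        return cls(
            probs=probs,
            observed=np.ones(16, dtype=bool),
            context_probs=np.asarray(context_probs, dtype=float),
        )

    def sample_codes(
        self,
        length: int,
        rng: np.random.Generator,
        reps: int = 1,
        pair_init: np.ndarray | None = None,
    ) -> np.ndarray:
        """Simulate ``reps`` sequences of ``length`` bases as code arrays.

        The first two bases are drawn from ``pair_init`` (default: the
        model's own context distribution); each later base from the row of
        its two predecessors.  Unobserved contexts fall back to a uniform
        draw.  Returns an array of shape ``(reps, length)``.
        """
        if length < 2:
            raise ValueError("length must be at least 2")
        if pair_init is None:
            pair_init = self.context_probs
        pair_init = np.asarray(pair_init, dtype=float)
        pair_init = pair_init / pair_init.sum()

        rows = np.where(
            self.observed[:, None], np.nan_to_num(self.probs, nan=0.25), 0.25
        )
        cum = np.cumsum(rows, axis=1)
        cum[:, -1] = 1.0  # guard against rounding

        out = np.empty((reps, length), dtype=np.uint8)
        ctx = rng.choice(16, size=reps, p=pair_init)
        out[:, 0] = ctx // 4
        out[:, 1] = ctx % 4
        for i in range(2, length):
            u = rng.random(reps)
            nxt = (u[:, None] > cum[ctx]).sum(axis=1).astype(np.uint8)
            out[:, i] = nxt
            ctx = (out[:, i - 1].astype(np.intp) * 4) + nxt
        return out


def _window_counts(codes: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    m = codes.shape[0] - n + 1
    if m <= 0:
        raise ValueError(f"genome shorter than n={n}")
    idx = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for i in range(n):
        c = codes[i : i + m]
        valid = c < 4
        ok &= valid
        idx = idx * 4 + np.where(valid, c, 0)
    wc = int(ok.sum())
    if wc == 0:
        raise ValueError("no window free of non-ACGT characters")
    counts = np.bincount(idx[ok], minlength=4**n)
    return counts, wc


def tuple_distribution(genome: Genome | np.ndarray, n: int) -> TupleDistribution:
    """The length-n word distribution of a genome.

    Accepts a :class:`~fragilome.seqio.Genome` or a raw code array.  Counts
    every contiguous length-n window consisting solely of A/C/G/T and
    normalizes by the number of such windows.
    """
    if not 1 <= n <= MAX_N:
        raise ValueError(f"n must be in 1..{MAX_N}")
    codes = genome.codes() if isinstance(genome, Genome) else genome
    counts, wc = _window_counts(codes, n)
    return TupleDistribution(n=n, probs=counts / wc, window_count=wc)


def transition_matrix(genome: Genome | np.ndarray) -> TransitionMatrix:
    """Second-order Markov transition matrix estimated from triplet counts.

    Entry (b1 b2, b3) is count(b1 b2 b3) / count(b1 b2 as the prefix of any
    counted triplet window).  Requires |G| >= 3.
    """
    codes = genome.codes() if isinstance(genome, Genome) else genome
    counts, wc = _window_counts(codes, 3)
    triplet = counts.reshape(16, 4).astype(float)
    prefix = triplet.sum(axis=1)
    observed = prefix > 0
    probs = np.full((16, 4), np.nan)
    probs[observed] = triplet[observed] / prefix[observed, None]
    return TransitionMatrix(
        probs=probs, observed=observed, context_probs=prefix / wc
    )
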