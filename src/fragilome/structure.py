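"""Higher-order genome structure: repeats and reverse-complement palindromes.

Long exact repeats and genomic palindromes (a sequence immediately
followed by its reverse complement) are the most fragile features under
degradation: a handful of substitutions destroys an exact long repeat,
while very short palindromes occur at the random-sequence rate and are
both destroyed and created by mutation.  The decay tables produced here
track feature counts across degradation checkpoints.

Counting conventions (both are >=-threshold, so counts are nested):

* repeats: the number of length-L windows whose exact sequence occurs at
  least twice in the genome (occurrence count, same strand only);
* palindromes: the number of center positions whose flanks match as
  ``s || revcomp(s)`` with half-length at least h (even-length, gapless).

Windows or flanks containing a non-ACGT character are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .degrade import MutationConfig, iter_degraded
from .seqio import Genome

__all__ = [
    "StructureDecayTable",
    "count_repeats",
    "count_palindromes",
    "structure_decay",
]

FEATURES = ("repeat", "palindrome")


@dataclass(frozen=True)
class StructureDecayTable:
    """Feature counts (rows: iterations, columns: length thresholds)."""

    feature: str
    thresholds: tuple[int, ...]
    iterations: tuple[int, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"feature must be one of {FEATURES}")
        if self.counts.shape != (len(self.iterations), len(self.thresholds)):
            raise ValueError("counts shape must be iterations x thresholds")
        if (np.diff(self.counts.astype(np.int64), axis=1) > 0).any():
            raise ValueError("counts must be nonincreasing across thresholds")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.iterations, name="iteration"),
            columns=pd.Index(self.thresholds, name=self.feature),
        )


def _codes(genome: Genome | np.ndarray) -> np.ndarray:
    return genome.codes() if isinstance(genome, Genome) else genome


def count_repeats(genome: Genome | np.ndarray, length: int) -> int:
    """Number of length-``length`` windows whose sequence occurs >= 2 times.

    Occurrence convention: every window position of a non-unique word
    counts (self-overlapping occurrences included).  Same strand only.
    """
    codes = _codes(genome)
    if length < 1:
        raise ValueError("length must be positive")
    if length > codes.shape[0]:
        raise ValueError(f"length {length} exceeds genome length {codes.shape[0]}")
    win = sliding_window_view(codes, length)
    ok = (win < 4).all(axis=1)
    valid = np.ascontiguousarray(win[ok])
    if valid.shape[0] == 0:
        return 0
    view = valid.view([("", valid.dtype)] * length).ravel()
    _, inverse, counts = np.unique(view, return_inverse=True, return_counts=True)
    return int((counts[inverse] >= 2).sum())


def count_palindromes(genome: Genome | np.ndarray, half_length: int) -> int:
    """Number of centers flanked by ``s || revcomp(s)`` with half-length >= h.

    A center sits between two adjacent bases; the h bases to its left must
    be the reverse complement of the h bases to its right.  Centers whose
    flanks contain a non-ACGT character are skipped.
    """
    if half_length < 1:
        raise ValueError("half_length must be positive")
    codes = _codes(genome)
    n = codes.shape[0]
    if n < 2 * half_length:
        raise ValueError(
            f"genome length {n} shorter than 2 x half_length {half_length}"
        )
    h = half_length
    m = n - 2 * h + 1  # centers i = h .. n-h
    acc = np.ones(m, dtype=bool)
    for j in range(h):
        right = codes[h + j : h + j + m]
        left = codes[h - 1 - j : h - 1 - j + m]
        acc &= (right < 4) & (left < 4) & (right == 3 - left)
    return int(acc.sum())


def structure_decay(
    genome: Genome,
    config: MutationConfig,
    iterations: Sequence[int] = (0, 100, 200, 300, 400, 500),
    thresholds: Sequence[int] = (20, 25, 29, 35, 40),
    feature: str = "repeat",
) -> StructureDecayTable:
    """Tabulate repeat or palindrome counts across degradation checkpoints.

    Row r holds the counts on the degraded snapshot at iteration r (row 0
    is the input genome); columns are length thresholds (repeats) or
    half-lengths (palindromes).
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    counter = count_repeats if feature == "repeat" else count_palindromes
    its = tuple(int(i) for i in iterations)
    ths = tuple(int(t) for t in thresholds)
    table = np.zeros((len(its), len(ths)), dtype=np.int64)
    cap = max(max(its), 2000)
    for row, (_, codes) in enumerate(
        iter_degraded(genome.codes(), config, its, max_iterations=cap)
    ):
        for col, t in enumerate(ths):
            table[row, col] = counter(codes, t)
    return StructureDecayTable(
        feature=feature, thresholds=ths, iterations=its, counts=table
    )
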