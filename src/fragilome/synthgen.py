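"""Synthetic genomes and databases with planted ground truth.

The generator emulates the structure of a real genome database on which
degradation-based outlier detection is exercised: a bulk population of
similar genomes descended from one second-order Markov template, a handful
of heavily degraded copies of bulk members ("low-quality" plants), and one
unrelated iid genome — mirroring a large coronavirus database spiked with
ten degraded coronaviruses plus one adenovirus.  The emitted truth table
makes every pipeline stage testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import decode, reverse_complement
from .degrade import MutationConfig, degrade
from .ngram import TransitionMatrix
from .seqio import Genome

__all__ = [
    "DatabaseSpec",
    "random_genome",
    "markov_genome",
    "random_transition_matrix",
    "plant_feature",
    "build_database",
]

ROLES = ("bulk", "degraded_outlier", "foreign")

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class DatabaseSpec:
    """Recipe for a synthetic genome database with planted outliers.

    Defaults describe the study conditions the package is validated under:
    300 bulk genomes of 30 kb from a shared second-order Markov template,
    each diverged by SNPs at 5e-3 per base (distinct but one cluster); 10
    outliers made by 2000 iterations of heavy SNP-only degradation
    (:meth:`fragilome.degrade.MutationConfig.heavy`) of randomly chosen
    bulk members; and one foreign iid genome of 34,125 bases (the
    adenovirus-plant length; cosmetic).
    """

    n_bulk: int = 300
    genome_length: int = 30_000
    template_model: TransitionMatrix | None = None
    bulk_divergence: float = 5e-3
    n_degraded_outliers: int = 10
    outlier_iterations: int = 2000
    outlier_config: MutationConfig | None = None
    include_foreign: bool = True
    foreign_length: int = 34_125
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bulk < 2:
            raise ValueError("n_bulk must be at least 2")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be at least 1000")
        if not 0.0 <= self.bulk_divergence <= 1.0:
            raise ValueError("bulk_divergence must be in [0, 1]")
        if self.n_degraded_outliers > self.n_bulk:
            raise ValueError("cannot degrade more outliers than bulk members")


def random_genome(
    length: int,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
    id: str = "random",
) -> Genome:
    """iid random genome with the given base probabilities."""
    p = np.asarray(base_probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return Genome(id=id, sequence=decode(codes))


def random_transition_matrix(
    seed: int | np.random.Generator = 0, concentration: float = 1.0
) -> TransitionMatrix:
    """A random second-order Markov model with Dirichlet rows.

    ``concentration`` 1 gives rows of moderate bias, so that genomes drawn
    from the model have triplet entropy well below the 6-bit maximum and
    therefore visibly gain entropy under degradation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = rng.dirichlet([concentration] * 4, size=16)
    return TransitionMatrix.from_rows(rows)


def markov_genome(
    length: int,
    model: TransitionMatrix,
    pair_init: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    id: str = "markov",
) -> Genome:
    """One genome simulated from a second-order Markov model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = None if pair_init is None else np.asarray(pair_init, dtype=float)
    codes = model.sample_codes(length, rng, reps=1, pair_init=init)[0]
    return Genome(id=id, sequence=decode(codes))


def plant_feature(
    genome: Genome,
    kind: str,
    unit_length: int,
    copies: int,
    seed: int | np.random.Generator = 0,
) -> tuple[Genome, list[int]]:
    """Overwrite segments of a genome with a planted repeat or palindrome.

    ``repeat``: one random ``unit_length``-mer written at ``copies``
    non-overlapping random positions.  ``palindrome``: ``copies``
    independent ``s + revcomp(s)`` blocks (half-length ``unit_length``)
    each written once.  Returns the modified genome and the 0-based start
    positions of the planted blocks.
    """
    if kind not in ("repeat", "palindrome"):
        raise ValueError("kind must be 'repeat' or 'palindrome'")
    block = unit_length if kind == "repeat" else 2 * unit_length
    if copies * block >= genome.length / 10:
        raise ValueError("planted material must stay under 10% of the genome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = bytearray(genome.sequence.encode("ascii"))
    if copies == 0:
        return genome, []

    unit = decode(rng.integers(0, 4, size=unit_length).astype(np.uint8))
    positions: list[int] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(positions) < copies:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place non-overlapping copies")
        start = int(rng.integers(0, genome.length - block + 1))
        if any(start < e and start + block > s for s, e in taken):
            continue
        if kind == "repeat":
            payload = unit
        else:
            s = decode(rng.integers(0, 4, size=unit_length).astype(np.uint8))
            payload = s + reverse_complement(s)
        seq[start : start + block] = payload.encode("ascii")
        taken.append((start, start + block))
        positions.append(start)
    return Genome(id=genome.id, sequence=seq.decode("ascii")), sorted(positions)


def build_database(spec: DatabaseSpec) -> tuple[list[Genome], pd.DataFrame]:
    """Generate the database and its ground-truth table.

    Returns the genomes (bulk, then degraded outliers, then the foreign
    genome) and a truth table with columns ``genome_id``, ``role`` (one of
    ``bulk``/``degraded_outlier``/``foreign``), ``parent_id`` (for
    degraded outliers) and the per-member ``seed`` used to generate it.
    Same spec (incl. seed) -> byte-identical output.
    """
    master = np.random.default_rng(spec.seed)
    model = spec.template_model or random_transition_matrix(
        int(master.integers(_SEED_CAP))
    )
    template_seed = int(master.integers(_SEED_CAP))
    template = markov_genome(
        spec.genome_length, model, seed=template_seed, id="template"
    )

    genomes: list[Genome] = []
    rows: list[dict] = []
    width = len(str(max(spec.n_bulk, 1)))
    diverge = MutationConfig(
        snp_rate=spec.bulk_divergence, ins_rate=0.0, del_rate=0.0
    )
    for i in range(spec.n_bulk):
        s = int(master.integers(_SEED_CAP))
        g = Genome(
            id=f"bulk_{i + 1:0{width}d}",
            sequence=degrade(
                template, diverge.with_seed(s), checkpoints=(0, 1)
            )[1][1].sequence,
        )
        genomes.append(g)
        rows.append(
            {"genome_id": g.id, "role": "bulk", "parent_id": "template", "seed": s}
        )

    heavy = spec.outlier_config or MutationConfig.heavy()
    picks = master.choice(spec.n_bulk, size=spec.n_degraded_outliers, replace=False)
    for j, idx in enumerate(sorted(int(x) for x in picks)):
        s = int(master.integers(_SEED_CAP))
        parent = genomes[idx]
        snap = degrade(
            parent,
            heavy.with_seed(s),
            checkpoints=(0, spec.outlier_iterations),
            max_iterations=max(spec.outlier_iterations, 2000),
        )[1][1]
        g = Genome(id=f"degraded_{j + 1:02d}", sequence=snap.sequence)
        genomes.append(g)
        rows.append(
            {
                "genome_id": g.id,
                "role": "degraded_outlier",
                "parent_id": parent.id,
                "seed": s,
            }
        )

    if spec.include_foreign:
        s = int(master.integers(_SEED_CAP))
        g = random_genome(spec.foreign_length, seed=s, id="foreign_01")
        genomes.append(g)
        rows.append(
            {"genome_id": g.id, "role": "foreign", "parent_id": "", "seed": s}
        )

    truth = pd.DataFrame(rows, columns=["genome_id", "role", "parent_id", "seed"])
    return genomes, truth
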