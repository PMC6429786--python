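"""Seeded generator of benchmark reads for the complexity filter.

Two read classes emulate the ends of the complexity spectrum seen in
short-read metagenomic QC:

* *repeat reads* — tandem repetitions of a short random unit (1-8 bp by
  default), modelling microsatellite-derived reads, with an optional
  i.i.d. substitution error sprinkled on top;
* *random reads* — i.i.d. uniform A/C/G/T, modelling high-complexity
  (coding-like) sequence.

With the default scorer (k = 4) a substitution-free repeat of unit length
u has exactly u distinct k-mers, score u/L, far below the 0.55 filter
threshold, while a uniform random 100-mer has expected score
256 * (1 - (255/256)**97) / 100 ~ 0.81.  The two score distributions are
therefore well separated, which is the property the benchmark exercises.

The generator produces single 100-nt reads only: scoring is per read, so
no insert-size or quality model is needed.  Real microsatellite records
carry unique flanking sequence that pure tandem repeats do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import SequenceRecord, write_reads

__all__ = [
    "SimSpec",
    "expected_random_score",
    "make_repeat_read",
    "make_random_read",
    "make_benchmark",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Benchmark parameters.

    n_reads reads per class, each read_length bases (default 100, the
    Illumina short-read length emulated).  Repeat units are drawn
    uniformly from 1..max_unit_length bases; substitution_rate is the
    per-base i.i.d. error probability.  The same seed always produces
    byte-identical output.
    """

    n_reads: int = 5500
    read_length: int = 100
    max_unit_length: int = 8
    substitution_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 1 <= self.max_unit_length:
            raise ValueError("max_unit_length must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")


def expected_random_score(read_length: int = 100, k: int = 4) -> float:
    """Closed-form expected complexity score of a uniform random read.

    Each of the 4**k possible k-mers is missed by all L - k + 1 draws with
    probability (1 - 4**-k)**(L-k+1) (treating k-mer occurrences as
    independent, a good approximation for k << L), so

        E[score] = 4**k * (1 - (1 - 4**-k)**(L-k+1)) / L.
    """
    n_kmers = 4**k
    n_draws = read_length - k + 1
    if n_draws <= 0:
        return 0.0
    expected_unique = n_kmers * (1.0 - (1.0 - 1.0 / n_kmers) ** n_draws)
    return expected_unique / read_length


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions; each hit base becomes one of the other 3."""
    if rate <= 0.0:
        return seq
    hits = rng.random(seq.size) < rate
    if not hits.any():
        return seq
    shift = rng.integers(1, 4, size=int(hits.sum()))
    idx = np.searchsorted(np.array(list("ACGT")), seq[hits])
    seq = seq.copy()
    seq[hits] = _BASES[(idx + shift) % 4]
    return seq


def make_repeat_read(
    unit_length: int,
    spec: SimSpec,
    rng: np.random.Generator,
    read_id: str = "repeat",
) -> SequenceRecord:
    """A tandem repeat of a random `unit_length`-mer, truncated to
    read_length, with substitutions at spec.substitution_rate."""
    if not 1 <= unit_length <= spec.max_unit_length:
        raise ValueError(
            f"unit_length must be in 1..{spec.max_unit_length}, got {unit_length}"
        )
    unit = rng.choice(_BASES, size=unit_length)
    n_copies = -(-spec.read_length // unit_length)
    seq = np.tile(unit, n_copies)[: spec.read_length]
    seq = _substitute(seq, spec.substitution_rate, rng)
    return SequenceRecord(read_id, "".join(seq))


def make_random_read(
    spec: SimSpec, rng: np.random.Generator, read_id: str = "random"
) -> SequenceRecord:
    """An i.i.d. uniform A/C/G/T read of spec.read_length bases."""
    return SequenceRecord(read_id, "".join(rng.choice(_BASES, size=spec.read_length)))


def make_benchmark(
    spec: SimSpec,
    out_low: str | Path,
    out_high: str | Path,
) -> tuple[int, int]:
    """Write the two-class benchmark as FASTA; returns (n_low, n_high).

    `out_low` receives n_reads tandem-repeat reads (unit lengths cycling
    through 1..max_unit_length), `out_high` n_reads uniform random reads.
    Byte-identical output for identical spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    low = []
    for i in range(spec.n_reads):
        unit_length = i % spec.max_unit_length + 1
        low.append(make_repeat_read(unit_length, spec, rng, f"repeat_{i}_u{unit_length}"))
    high = [make_random_read(spec, rng, f"random_{i}") for i in range(spec.n_reads)]
    n_low = write_reads(low, out_low, "fasta")
    n_high = write_reads(high, out_high, "fasta")
    return n_low, n_high
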