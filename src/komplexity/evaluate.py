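"""Benchmark metrics for masking tools.

Three analyses:

* :func:`masked_fraction` — fraction of nucleotides changed between an
  original and a masked read stream (the per-dataset "nucleotides masked"
  benchmark column);
* :func:`overlap_counts` — exclusive masked-position counts per tool
  combination, the partition behind UpSet-style comparisons of masking
  tools, plus per-tool totals and share-of-union fractions;
* :func:`score_distribution` — histogram and summary of whole-read
  complexity scores.

Masked positions are keyed by (read id, 0-based offset).  A position
counts as masked when the masked character differs from the original,
either by hard replacement or by lowercasing; an original 'N' that stays
'N' is undetectable and not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ComplexityParams, score_read
from .io import SequenceRecord

__all__ = [
    "EvalSummary",
    "OverlapTable",
    "masked_fraction",
    "overlap_counts",
    "score_distribution",
]


@dataclass(frozen=True)
class EvalSummary:
    """Dataset-level masking summary."""

    label: str
    total_bases: int
    masked_bases: int
    reads_total: int
    reads_fully_masked: int

    @property
    def masked_fraction(self) -> float:
        return self.masked_bases / self.total_bases if self.total_bases else 0.0


@dataclass(frozen=True)
class OverlapTable:
    """Exclusive masked-position counts per non-empty tool combination.

    ``exclusive`` maps a sorted tuple of tool names to the number of
    positions masked by exactly that set of tools; the counts partition
    the union of all tools' masked positions.  ``totals`` gives each
    tool's overall masked-position count and ``union_size`` the size of
    the union.
    """

    exclusive: dict[tuple[str, ...], int]
    totals: dict[str, int]
    union_size: int

    def share_of_union(self, tool: str) -> float:
        """Fraction of the union masked by `tool` (alone or with others)."""
        if self.union_size == 0:
            return 0.0
        return self.totals[tool] / self.union_size

    def to_frame(self) -> pd.DataFrame:
        """Long-format table consumable by UpSet plotting tools."""
        rows = [
            {"combination": "&".join(combo), "degree": len(combo), "count": n}
            for combo, n in sorted(
                self.exclusive.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def _is_masked(orig: str, masked: str) -> bool:
    return masked != orig


def masked_fraction(
    original: Iterable[SequenceRecord],
    masked: Iterable[SequenceRecord],
    label: str = "",
) -> EvalSummary:
    """Count positions where `masked` differs from `original`.

    Streams must be paired: same read ids in the same order, equal
    sequence lengths per read.  Hard-masked (character replaced) and
    soft-masked (lowercased) positions both count.
    """
    total = 0
    changed = 0
    reads = 0
    fully = 0
    sentinel = object()
    for orig, msk in zip_longest(original, masked, fillvalue=sentinel):
        if orig is sentinel or msk is sentinel:
            raise ValueError("original and masked streams have different lengths")
        if orig.read_id != msk.read_id:
            raise ValueError(
                f"read id mismatch: {orig.read_id!r} vs {msk.read_id!r}"
            )
        if len(orig.sequence) != len(msk.sequence):
            raise ValueError(
                f"record {orig.read_id!r}: sequence lengths differ "
                f"({len(orig.sequence)} vs {len(msk.sequence)})"
            )
        n_changed = sum(
            a != b for a, b in zip(orig.sequence, msk.sequence)
        )
        total += len(orig.sequence)
        changed += n_changed
        reads += 1
        if orig.sequence and n_changed == len(orig.sequence):
            fully += 1
    return EvalSummary(
        label=label,
        total_bases=total,
        masked_bases=changed,
        reads_total=reads,
        reads_fully_masked=fully,
    )


def overlap_counts(
    masked_positions: Mapping[str, set[tuple[str, int]]]
) -> OverlapTable:
    """Partition the union of masked positions by tool-membership pattern.

    `masked_positions` maps tool name -> set of (read id, 0-based offset)
    pairs.  Each position in the union is assigned to exactly one
    combination: the set of tools that masked it.
    """
    if not masked_positions:
        raise ValueError("at least one tool is required")
    if any(not name for name in masked_positions):
        raise ValueError("tool names must be non-empty")
    tools = sorted(masked_positions)
    union: set[tuple[str, int]] = set()
    for positions in masked_positions.values():
        union |= positions
    exclusive: dict[tuple[str, ...], int] = {}
    for pos in union:
        combo = tuple(t for t in tools if pos in masked_positions[t])
        exclusive[combo] = exclusive.get(combo, 0) + 1
    totals = {t: len(masked_positions[t]) for t in tools}
    return OverlapTable(exclusive=exclusive, totals=totals, union_size=len(union))


def score_distribution(
    reads: Iterable[SequenceRecord],
    params: ComplexityParams | None = None,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Histogram of whole-read complexity scores over [0, 1].

    Returns ``(edges, counts, summary)`` with `bins` equal-width bins
    (right-open except the last, numpy convention) and summary statistics
    mean and median.  Counts sum to the number of reads.
    """
    params = params or ComplexityParams()
    scores = np.array(
        [score_read(r.read_id, r.sequence, params).score for r in reads]
    )
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    summary = {
        "n": float(scores.size),
        "mean": float(scores.mean()) if scores.size else 0.0,
        "median": float(np.median(scores)) if scores.size else 0.0,
    }
    return edges, counts, summary
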