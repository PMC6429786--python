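"""k-mer complexity scoring, windowed masking, and read-filter decisions.

The complexity score of a nucleotide sequence is the number of distinct
k-mers it contains divided by its length.  A homopolymer of length L has a
single k-mer and scores 1/L; a read of L i.i.d. uniform bases scores close
to (L - k + 1)/L for small k.  Low scores therefore flag repetitive,
low-complexity sequence (homopolymers, microsatellites) that causes
spurious hits in downstream classification and assembly.

Only k-mers consisting entirely of A/C/G/T (case-folded) are counted;
k-mers containing any other character (N, ambiguity codes, gaps) are
skipped, so an all-N read scores 0.  Counting is strand-specific: a k-mer
and its reverse complement are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ComplexityParams",
    "ScoreRecord",
    "MaskResult",
    "unique_kmer_count",
    "complexity_score",
    "window_scores",
    "mask",
    "should_remove",
    "score_read",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ComplexityParams:
    """Tunables of the complexity filter.

    Parameters
    ----------
    k : int
        k-mer length in bases, >= 1.  Default 4.
    window : int
        Sliding-window length in bases for masking, >= k.  Default 32.
    threshold : float
        Complexity-score cutoff in [0, 1].  Windows (for masking) or whole
        reads (for filtering) scoring strictly below it are masked/removed.
        Default 0.55.
    mask_style : str
        ``"hard"`` replaces masked bases with `mask_char`; ``"soft"``
        lowercases them.
    mask_char : str
        Replacement character for hard masking.  Default ``"N"``.
    """

    k: int = 4
    window: int = 32
    threshold: float = 0.55
    mask_style: str = "hard"
    mask_char: str = "N"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.window < self.k:
            raise ValueError(
                f"window ({self.window}) must be >= k ({self.k})"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(
                f"threshold must be in [0, 1], got {self.threshold}"
            )
        if self.mask_style not in ("hard", "soft"):
            raise ValueError(
                f"mask_style must be 'hard' or 'soft', got {self.mask_style!r}"
            )
        if len(self.mask_char) != 1:
            raise ValueError("mask_char must be a single character")


@dataclass(frozen=True)
class ScoreRecord:
    """Whole-read complexity summary: ``score = unique_kmers / length``."""

    read_id: str
    length: int
    unique_kmers: int
    score: float


@dataclass(frozen=True)
class MaskResult:
    """A masked sequence plus the 0-based half-open intervals masked.

    ``sequence`` has the same length as the input; positions outside
    ``intervals`` are byte-identical to the input.  Intervals are sorted,
    non-overlapping and merged; ``masked_bases`` is their total length.
    """

    sequence: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def masked_bases(self) -> int:
        return sum(end - start for start, end in self.intervals)


def _encode(seq: str) -> list[int]:
    """Map bases to 0..3 (case-folded A/C/G/T) or -1 (anything else)."""
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "a": 0, "c": 1, "g": 2, "t": 3}
    return [table.get(ch, -1) for ch in seq]


def _kmer_codes(seq: str, k: int) -> list[int]:
    """Integer code of the k-mer starting at each position, -1 if invalid.

    Valid k-mers are packed 2 bits per base; a k-mer overlapping any
    non-ACGT character is coded -1.  Rolling computation, O(len(seq)).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(seq)
    if n < k:
        return []
    enc = _encode(seq)
    codes = [-1] * (n - k + 1)
    mask_bits = (1 << (2 * k)) - 1
    code = 0
    valid_run = 0  # length of current run of valid bases ending here
    for i, b in enumerate(enc):
        if b < 0:
            valid_run = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask_bits
        valid_run += 1
        if valid_run >= k:
            codes[i - k + 1] = code
    return codes


def unique_kmer_count(seq: str, k: int) -> int:
    """Number of distinct A/C/G/T k-mers in `seq` (case-insensitive).

    k-mers containing any non-ACGT character are skipped.  Returns 0 when
    the sequence is shorter than k.  Raises ``ValueError`` for k < 1.
    """
    codes = _kmer_codes(seq, k)
    return len({c for c in codes if c >= 0})


def complexity_score(seq: str, k: int) -> float:
    """Unique k-mer count divided by sequence length; 0 for an empty seq.

    Note the denominator is the full sequence length L, not the number of
    k-mer positions L - k + 1, so the score never reaches 1.0 for L >= k.
    """
    if not seq:
        return 0.0
    return unique_kmer_count(seq, k) / len(seq)


def score_read(read_id: str, seq: str, params: ComplexityParams) -> ScoreRecord:
    """Build the whole-read :class:`ScoreRecord` for one sequence."""
    n_unique = unique_kmer_count(seq, params.k) if len(seq) >= params.k else 0
    score = n_unique / len(seq) if seq else 0.0
    return ScoreRecord(read_id=read_id, length=len(seq),
                       unique_kmers=n_unique, score=score)


def window_scores(
    seq: str, params: ComplexityParams
) -> list[tuple[int, float]]:
    """Complexity score of every length-`window` substring, step 1.

    Returns ``(start, score)`` pairs for start = 0 .. L - window.  A
    non-empty sequence shorter than the window yields a single entry
    ``(0, complexity_score(seq, k))``; an empty sequence yields [].
    """
    n = len(seq)
    if n == 0:
        return []
    w, k = params.window, params.k
    if n < w:
        return [(0, complexity_score(seq, k))]
    codes = _kmer_codes(seq, k)
    kmers_per_window = w - k + 1
    # rolling multiset of k-mer codes inside the current window
    counts: dict[int, int] = {}
    distinct = 0
    out: list[tuple[int, float]] = []
    for start in range(n - w + 1):
        if start == 0:
            for c in codes[:kmers_per_window]:
                if c >= 0:
                    counts[c] = counts.get(c, 0) + 1
                    if counts[c] == 1:
                        distinct += 1
        else:
            old = codes[start - 1]
            if old >= 0:
                counts[old] -= 1
                if counts[old] == 0:
                    distinct -= 1
            new = codes[start + kmers_per_window - 1]
            if new >= 0:
                counts[new] = counts.get(new, 0) + 1
                if counts[new] == 1:
                    distinct += 1
        out.append((start, distinct / w))
    return out


def _merge_intervals(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def mask(seq: str, params: ComplexityParams) -> MaskResult:
    """Mask every position covered by a sub-threshold window.

    The masked region is the merged union of all windows whose score falls
    strictly below ``params.threshold``.  Hard masking replaces bases with
    ``params.mask_char``; soft masking lowercases them.  All other
    positions are returned unchanged (original case preserved).
    """
    n = len(seq)
    scores = window_scores(seq, params)
    win = min(params.window, n) if n else 0
    raw = [
        (start, start + win)
        for start, score in scores
        if score < params.threshold
    ]
    intervals = _merge_intervals(raw)
    if not intervals:
        return MaskResult(sequence=seq, intervals=[])
    chars = list(seq)
    for start, end in intervals:
        for i in range(start, end):
            chars[i] = (
                chars[i].lower()
                if params.mask_style == "soft"
                else params.mask_char
            )
    return MaskResult(sequence="".join(chars), intervals=intervals)


def should_remove(seq: str, params: ComplexityParams) -> bool:
    """True iff the whole-read complexity score falls below the threshold.

    The comparison is strict, so a score exactly equal to the threshold is
    kept.  Reads shorter than k score 0 and are removed for any positive
    threshold.
    """
    return complexity_score(seq, params.k) < params.threshold
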