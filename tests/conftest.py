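"""Shared fixtures and independent brute-force oracles.

The oracles recompute k-mer counts, window scores and mask intervals by
naive substring-set enumeration, independent of the rolling-hash
implementation under test.
"""

from __future__ import annotations

import random

import pytest

VALID = set("ACGT")


def naive_unique_kmers(seq: str, k: int) -> int:
    """Distinct valid k-mers by explicit substring enumeration."""
    seq = seq.upper()
    kmers = {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if set(seq[i : i + k]) <= VALID
    }
    return len(kmers)


def naive_score(seq: str, k: int) -> float:
    return naive_unique_kmers(seq, k) / len(seq) if seq else 0.0


def naive_window_scores(seq: str, k: int, window: int) -> list[tuple[int, float]]:
    if not seq:
        return []
    if len(seq) < window:
        return [(0, naive_score(seq, k))]
    return [
        (s, naive_unique_kmers(seq[s : s + window], k) / window)
        for s in range(len(seq) - window + 1)
    ]


def naive_mask_intervals(
    seq: str, k: int, window: int, threshold: float
) -> list[tuple[int, int]]:
    """Merged union of sub-threshold windows, via a per-position flag array."""
    n = len(seq)
    win = min(window, n)
    flagged = [False] * n
    for start, score in naive_window_scores(seq, k, window):
        if score < threshold:
            for i in range(start, start + win):
                flagged[i] = True
    intervals = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return intervals


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(42)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="reads.fasta"):
        path = tmp_path / name
        with open(path, "w") as out:
            for rid, seq in records:
                out.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_fastq(tmp_path):
    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as out:
            for rid, seq in records:
                out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    return _write
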