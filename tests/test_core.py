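"""Unit tests for the complexity scorer, windowed masking and filtering."""

import random

import pytest

from komplexity.core import (
    ComplexityParams,
    complexity_score,
    mask,
    score_read,
    should_remove,
    unique_kmer_count,
    window_scores,
)

from conftest import (
    naive_mask_intervals,
    naive_score,
    naive_unique_kmers,
    naive_window_scores,
    random_seq,
)

DEFAULTS = ComplexityParams()


class TestParams:
    def test_defaults(self):
        assert (DEFAULTS.k, DEFAULTS.window, DEFAULTS.threshold) == (4, 32, 0.55)
        assert DEFAULTS.mask_style == "hard"
        assert DEFAULTS.mask_char == "N"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 0},
            {"k": 8, "window": 4},
            {"threshold": -0.1},
            {"threshold": 1.5},
            {"mask_style": "both"},
            {"mask_char": "NN"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ComplexityParams(**kwargs)


class TestUniqueKmerCount:
    @pytest.mark.parametrize(
        "seq, k, expected",
        [
            ("AAAAAAAAAA", 4, 1),          # homopolymer: one k-mer
            ("ACGTACGTACGT", 4, 4),        # {ACGT, CGTA, GTAC, TACG}
            ("ACGNACGT", 4, 1),            # only ACGT is N-free
            ("ACG", 4, 0),                 # shorter than k
            ("", 4, 0),
            ("acgtacgtacgt", 4, 4),        # case-folded
            ("NNNNNNNN", 4, 0),            # no valid k-mer at all
            ("ACGT", 1, 4),
            ("AAAA", 1, 1),
        ],
    )
    def test_examples(self, seq, k, expected):
        assert unique_kmer_count(seq, k) == expected

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            unique_kmer_count("ACGT", 0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            length = rng.randrange(0, 120)
            seq = random_seq(rng, length, "ACGTNacgtn")
            k = rng.choice([1, 2, 3, 4, 5, 8])
            assert unique_kmer_count(seq, k) == naive_unique_kmers(seq, k), (
                seq,
                k,
            )


class TestComplexityScore:
    def test_homopolymer_100(self):
        assert complexity_score("A" * 100, 4) == pytest.approx(0.01)

    def test_period_four_repeat(self):
        assert complexity_score("ACGTACGTACGT", 4) == pytest.approx(4 / 12)

    def test_empty_sequence_scores_zero(self):
        assert complexity_score("", 4) == 0.0

    def test_score_bound_and_equality(self, rng):
        # score <= (L-k+1)/L, equality iff all k-mers distinct
        for _ in range(100):
            length = rng.randrange(4, 80)
            seq = random_seq(rng, length)
            score = complexity_score(seq, 4)
            bound = (length - 3) / length
            assert score <= bound + 1e-12
        assert complexity_score("ACGTTGCA", 4) == pytest.approx(5 / 8)


class TestWindowScores:
    def test_single_window_homopolymer(self):
        assert window_scores("A" * 32, DEFAULTS) == [(0, 1 / 32)]

    def test_two_windows_homopolymer(self):
        assert window_scores("A" * 33, DEFAULTS) == [(0, 1 / 32), (1, 1 / 32)]

    def test_short_sequence_single_entry(self):
        seq = "ACGTACGT"
        assert window_scores(seq, DEFAULTS) == [(0, complexity_score(seq, 4))]

    def test_empty_sequence(self):
        assert window_scores("", DEFAULTS) == []

    def test_random_64mer_matches_oracle(self):
        rng = random.Random(7)
        seq = random_seq(rng, 64)
        result = window_scores(seq, DEFAULTS)
        assert len(result) == 33
        assert result == pytest.approx(naive_window_scores(seq, 4, 32))

    def test_oracle_equivalence_with_invalid_chars(self, rng):
        for _ in range(50):
            seq = random_seq(rng, rng.randrange(0, 100), "ACGTN")
            got = window_scores(seq, DEFAULTS)
            expected = naive_window_scores(seq, 4, 32)
            assert [s for s, _ in got] == [s for s, _ in expected]
            assert [x for _, x in got] == pytest.approx([x for _, x in expected])


class TestMask:
    def test_homopolymer_fully_masked(self):
        result = mask("A" * 100, DEFAULTS)
        assert result.sequence == "N" * 100
        assert result.intervals == [(0, 100)]
        assert result.masked_bases == 100

    def test_high_complexity_read_untouched(self):
        rng = random.Random(3)
        seq = random_seq(rng, 100)
        # premise: verify via oracle that every window clears the threshold
        assert all(s >= 0.55 for _, s in naive_window_scores(seq, 4, 32))
        result = mask(seq, DEFAULTS)
        assert result.sequence == seq
        assert result.intervals == []

    def test_mixed_read_matches_oracle_union(self):
        rng = random.Random(11)
        seq = "A" * 50 + random_seq(rng, 50)
        result = mask(seq, DEFAULTS)
        expected = naive_mask_intervals(seq, 4, 32, 0.55)
        assert result.intervals == expected
        assert expected[0][0] == 0 and expected[0][1] >= 50  # prefix masked

    def test_soft_mask_lowercases(self):
        params = ComplexityParams(mask_style="soft")
        result = mask("A" * 40 + "ACGTTGCATGGC" * 5, params)
        for (start, end) in result.intervals:
            assert result.sequence[start:end].islower()

    def test_positions_outside_intervals_unchanged(self):
        rng = random.Random(5)
        seq = random_seq(rng, 60) + "T" * 40
        result = mask(seq, DEFAULTS)
        flagged = set()
        for start, end in result.intervals:
            flagged.update(range(start, end))
        for i, (a, b) in enumerate(zip(seq, result.sequence)):
            if i not in flagged:
                assert a == b

    def test_short_low_complexity_read_fully_masked(self):
        result = mask("ACACACACAC", DEFAULTS)  # 10 nt < window, score 0.2
        assert result.sequence == "N" * 10
        assert result.intervals == [(0, 10)]


class TestShouldRemove:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("A" * 100, True),             # 0.01 < 0.55
            ("ACGT" * 25, True),           # period 4 -> score 0.04
            ("ACG", True),                 # shorter than k, score 0
        ],
    )
    def test_low_complexity_removed(self, seq, expected):
        assert should_remove(seq, DEFAULTS) is expected

    def test_random_read_kept_matches_oracle(self):
        rng = random.Random(19)
        seq = random_seq(rng, 100)
        score = naive_score(seq, 4)
        assert score >= 0.55  # premise for this seed
        assert should_remove(seq, DEFAULTS) is False

    def test_score_equal_to_threshold_is_kept(self):
        seq = "ACGTACGTACGTACGTACGT"  # 4 unique 4-mers / 20 = 0.2
        params = ComplexityParams(threshold=0.2)
        assert should_remove(seq, params) is False


def test_score_read_record_fields():
    rec = score_read("r1", "A" * 100, DEFAULTS)
    assert (rec.read_id, rec.length, rec.unique_kmers) == ("r1", 100, 1)
    assert rec.score == pytest.approx(0.01)
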