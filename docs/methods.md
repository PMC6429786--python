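# Methods

## Complexity score

For a nucleotide sequence *s* of length *L* and k-mer size *k*, the
complexity score is the number of distinct length-*k* substrings of *s*
consisting entirely of case-folded A/C/G/T, divided by *L*. Distinctness
is over exact strings on the given strand; a k-mer and its reverse
complement are counted separately. Substrings containing any other
character (N, IUPAC ambiguity codes, gaps) are skipped entirely, so they
neither create new k-mers nor collide with existing ones; an all-N read
scores 0 and is always removed at any positive threshold.

Two conventions here were genuinely open and are fixed as follows:

* **Denominator.** The score divides by the full length *L* rather than
  the number of k-mer positions *L − k + 1*. Consequence: the score never
  reaches 1.0 for *L ≥ k*; the attainable maximum is (L − k + 1)/L, with
  equality exactly when all k-mers are distinct. The filter threshold
  (default 0.55) is calibrated for this convention.
* **Strand handling.** No canonical (reverse-complement) collapsing.
  Strand-specific counting is the simplest deterministic choice and keeps
  the score independent of any canonicalization order.

Useful exact laws, all enforced by tests:

* homopolymer of length *L ≥ k*: exactly one k-mer, score 1/*L*;
* perfect tandem repeat with unit length *u*: as many k-mers as the unit
  has distinct cyclic k-factors — exactly *u* (score *u/L*) whenever those
  factors are distinct, which holds for primitive units without a repeated
  cyclic factor (e.g. every unit with u ≤ 3 < k, and almost all short
  microsatellite units; `ACGACGAT` repeats a 4-mer at cyclic distance 3
  and is a counterexample with 7 rather than 8 distinct 4-mers);
* uniform random read: E[score] ≈ 4^k (1 − (1 − 4^−k)^(L−k+1)) / L,
  treating k-mer occurrences as independent — 0.8087 for L = 100, k = 4.

The implementation packs valid k-mers 2 bits per base and counts windows
with a rolling multiset, O(L) per read; tests compare it against a naive
substring-set enumeration oracle.

## Masking

Windowed masking slides a window of length *w* (default 32) across the
read at step 1 and scores each window with denominator *w*. Every
position covered by at least one window scoring strictly below the
threshold is masked; the reported intervals are the merged union of the
sub-threshold windows. Step 1 is the maximal-sensitivity deterministic
choice given that only a window length is specified. Reads shorter than
the window are scored as a single window with denominator equal to the
read length; reads shorter than *k* score 0. Hard masking writes `N`
(the convention downstream aligners and classifiers understand); soft
masking lowercases. Original case is preserved at all unmasked positions,
and unmasking a soft-masked read by case-folding restores the input.

## Filtering

Whole-read filtering removes a read when its whole-read score falls
strictly below the threshold ("falls below"), so a score exactly equal to
the threshold is kept. For paired-end input the pair is dropped when
either mate fails, which keeps the two output files synchronized — the
convention of QC pipelines that retain only intact pairs. The removal log
counts individual reads (a dropped pair contributes two).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| k | 4 | k-mer length in bases; 4 gives 256 possible k-mers, enough resolution to separate repeats from random sequence at read length ~100 |
| window | 32 | masking window in bases; short enough to localize a microsatellite tract inside a read |
| threshold | 0.55 | score cutoff; sits in the wide gap between tandem-repeat scores (≤ ~0.08 for units ≤ 8) and random-sequence scores (~0.81 at L = 100) |
| mask character | `N` | hard-mask replacement |

## Synthetic benchmark

The generator emulates a two-class, equal-size benchmark of 100-nt
Illumina-like reads: 5,500 tandem-repeat reads (random unit of length
1–8, repeated and truncated to 100 nt, i.i.d. substitutions at rate 0.01
by default) and 5,500 uniform-random reads, ~1.1 Mb in total. A fixed
seed yields byte-identical FASTA output. Substitutions only — no indels,
no quality-score or insert-size model — since scoring operates per read
and substitutions suffice to blur repeat boundaries without changing
class separability. The unit-length range 1–8 covers homopolymers through
the longest units that still score well below threshold (u/L ≤ 0.08).

What the synthetic classes do **not** emulate: real microsatellite reads
carry unique flanking sequence and sequencing-error profiles, and real
coding sequence is not uniform-random (codon bias, repeated domains). The
synthetic benchmark therefore demonstrates correct separation behaviour
of the scorer, not the masked-fraction percentages expected on the
archived read benchmark. On the synthetic classes the acceptance script
measures ~100% repeat-read removal and masking versus <1% for the random
class; on the archived benchmark (simulated from real microsatellite
records and conserved coding sequence, available at
https://zenodo.org/record/2541222, ~1.1 Mb) the reference masked
fractions are 54.6% (microsatellite) and 0.68% (coding). Because the
original scorer's denominator and window-step conventions are
unpublished, the reproduction test accepts ±5 and ±1 percentage points
respectively; it requires the dataset to be downloaded once to
`data/benchmark/` and fails with instructions when run offline.

## Evaluation metrics

* **Masked fraction** compares an original and a masked stream pairwise
  and counts changed positions. Both hard-masked (character replaced) and
  soft-masked (lowercased) positions count. Caveat: an original `N`
  masked to `N` is undetectable and not counted; for the benchmark
  classes, inputs are N-free, so this does not bias the fractions.
* **Overlap counts** key masked positions by (read id, 0-based offset)
  and assign each position in the union to exactly one tool combination —
  the set of tools that masked it. The combination counts partition the
  union exactly (tested by brute-force membership classification), and
  per-tool totals and share-of-union fractions are derived from the same
  keying, making cross-tool comparisons (UpSet plots, "tool X masks p% of
  everything masked by any tool") computable from any set of third-party
  masked outputs. Per-read-position keying is used; positions from
  different reads are never identified with each other even if they
  originate from one genomic locus.
* **Score distribution** bins whole-read scores into 50 equal-width bins
  on [0, 1] (right-open except the last, numpy convention).

## Numerical and degenerate-input conventions

* Empty sequence: score 0, no windows, empty mask, removed by any
  positive threshold.
* Threshold comparisons are strict (`<`) everywhere.
* Scores are printed with 4 decimal places (round-half-even), making
  score tables bit-reproducible.
* Score-table format: headered 4-column TSV (read_id, length,
  unique_kmers, score); the removal log is key–TAB–value lines.
* Multi-line FASTA is accepted on input; output FASTA is unwrapped, the
  record id is the text up to the first whitespace, and any remaining
  description is written back verbatim.

## Problem sizes used in tests

Property tests run a few hundred randomized examples per law (sequences
up to 300 nt); the acceptance checks use the full 5,500-reads-per-class
benchmark and 1,000-sequence oracle sweeps. The complete suite and the
acceptance script each finish in a few seconds on one CPU.

## Known limitations

* No entropy-based (Shannon) scoring variant, and no reimplementation of
  database- or heuristic-based maskers; those are comparators whose
  outputs the evaluation module consumes.
* No SAM/BAM, interleaved paired FASTQ, or bzip2/zstd support.
* Hardware-dependent throughput/memory comparisons are out of scope.
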