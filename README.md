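# komplexity

Low-complexity nucleotide sequences — homopolymers, microsatellites and
other short tandem repeats — generate spurious alignments in taxonomic
classification and assembly of shotgun metagenomic data. They are
especially troublesome in low-microbial-biomass, host-associated samples,
where host microsatellite reads are abundant and too polymorphic to remove
reliably by alignment against a single reference genome.

`komplexity` scores, masks and filters such sequences in streaming
FASTA/FASTQ (plain or gzipped), with memory use independent of file size.
The complexity score of a sequence *s* of length *L* is

```
score(s) = |{distinct k-mers of s over A/C/G/T}| / L
```

with defaults k = 4, sliding-window length w = 32, and threshold
t = 0.55. A homopolymer scores 1/L; a perfect tandem repeat of (primitive)
unit length u scores u/L; a uniform random 100-mer scores about 0.81.
k-mers containing non-ACGT characters are skipped, and counting is
case-insensitive and strand-specific.

Three modes:

* **score** — per-read (or per-window) complexity scores as TSV;
* **mask** — replace every position covered by a window scoring below t
  with `N` (or lowercase with `--lowercase`), preserving the input format;
* **filter** — drop whole reads whose score falls below t, keeping pairs
  synchronized for paired-end input and logging read counts.

The package also ships a seeded synthetic benchmark generator
(tandem-repeat vs. uniform-random 100-nt reads) and evaluation utilities:
masked-nucleotide fractions, exclusive masked-position counts per tool
combination (UpSet-style), and score histograms.

## Worked example

```sh
$ cat demo.fasta        # one TA microsatellite read, one coding-like read
>microsat_1
TATATATA...(TA x 50)
>coding_like_1
GATCCTGAACGGCTTAGCCATTCGCAGTATCGTAACGGCATTAGCGGTACATCCGGTTAACGGTCTTGATTCAGGCACCATGCTGAGCCGTTATCAGGACT

$ komplexity score demo.fasta
read_id	length	unique_kmers	score
microsat_1	100	2	0.0200
coding_like_1	101	77	0.7624
```

The TA repeat contains only two distinct 4-mers (`TATA`, `ATAT`), hence
2/100 = 0.02, far below the 0.55 cutoff; the coding-like read has 77
distinct 4-mers in 101 bases and passes comfortably.

```sh
$ komplexity mask demo.fasta -o demo.masked.fasta
demo.fasta: masked 100 bases in 2 reads

$ komplexity filter demo.fasta -o demo.kept.fasta --log demo.log
kept 1/2 reads (removed 1)
$ cat demo.log
input_reads	2
removed_reads	1
kept_reads	1
threshold	0.55
k	4
```

Masking replaced all 100 bases of the microsatellite read with `N` and
left the coding-like read untouched; filtering removed it outright.

The same operations are available as library functions:

```python
from komplexity import ComplexityParams, complexity_score, mask, should_remove

params = ComplexityParams()            # k=4, window=32, threshold=0.55
complexity_score("TA" * 50, k=4)       # 0.02
should_remove("TA" * 50, params)       # True
mask("A" * 40 + "GATCCTGAACGGCTTAGCC", params).intervals  # [(0, 40)]
```

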