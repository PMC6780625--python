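# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, what the synthetic generator does and does
not emulate, and the known limitations.

## K-mer genome-size estimation

Reads are decomposed into all k-length windows (default k = 17, the
standard survey choice); windows containing non-ACGT characters are
skipped, and each window is counted under its canonical form — the
lexicographic minimum of the k-mer and its reverse complement — because
sequencing reads are unstranded. The histogram of distinct k-mers by
depth has, for reasonably uniform coverage c and read length L, a main
peak near c·(L−k+1)/L; sequencing errors create a large spike of
near-singleton k-mers at depth 1–2. The estimator is

    genome size = total k-mer occurrences / peak depth,

with "total occurrences" the count of all valid windows (this
interpretation reproduces the published 1.165 Gb figure from the printed
totals 20,970,039,103 / 18). The error spike is excluded by a
`min_depth = 3` cutoff rather than valley detection: simpler, and exact
on the clean histograms this package targets. Peak ties break toward the
smaller depth for determinism. Counting is vectorised (rolling 2-bit
encodings via correlation; 4¹⁷ < 2⁵³ so float64 arithmetic is exact) and
in-memory; it is intended for desk-scale inputs (≤ ~10⁷ windows), not
83 Gb survey datasets. No heterozygosity or repeat decomposition of the
histogram is attempted (no GenomeScope-style mixture fitting).

## Assembly summary statistics

Nx is defined on the length set's own total (assembler convention): the
smallest L such that sequences ≥ L cover at least x % of the summed
length, computed with integer comparisons to avoid float thresholds.
Reported percentages (repeat fraction, TE fraction, annotation support,
anchored fraction) use half-away-from-zero rounding at the printed
precision, which reproduces the published 45.1 / 42.4 / 93.37 / 88.62 /
96.8 values from their printed numerators and denominators. The mean
scaffold count per pseudochromosome is floored (1256/24 → 52), matching
the published convention; the exact mean is also reported.

## Linkage-map anchoring

The module consumes an existing genetic map (linkage group and cM per
marker, plus a flanking sequence); it does not construct maps from
genotypes. Design choices, in pipeline order:

* **Placement** is by exact, unique substring match of the flank (or its
  reverse complement) across all scaffolds. Exactness makes the contract
  testable; markers that are absent or match more than once are dropped
  with a logged reason (data, not errors). Palindromic flanks count
  their forward match only.
* **Eligibility** requires ≥ 2 placed markers per scaffold (default
  `min_markers = 2`): one marker cannot orient a scaffold and is more
  likely to be a spurious placement.
* **Linkage group** is the majority vote of the scaffold's markers; a
  tied vote, or fewer than `min_markers` on the winning group, excludes
  the scaffold as conflicted (conflicts exclude, never split, a
  scaffold). Position is the median cM of the winning-group markers —
  robust to a single bad marker.
* **Orientation** is the sign of the Spearman rank correlation between
  marker bp offset and cM; all-equal cM gives '?', treated as '+' but
  flagged, so arbitrariness is never silent.
* **Ordering** is by ascending anchor cM, ties broken lexicographically
  by scaffold id for determinism.
* **Assembly**: scaffolds are joined with 100 bp unknown gaps, written
  as AGP 2.0 'U' records (`scaffold`/`yes`/`map` evidence). Coordinates
  are 0-based half-open internally and 1-based inclusive in AGP,
  liftover results and all emitted tables.
* **Liftover** mirrors intervals and flips strand on '-' scaffolds, so
  the lifted interval always spells the feature's sequence (up to
  strand) in the chromosome FASTA — verified as a round-trip property.

## AMP homology screen

Queries are peptides with class annotations in `>ID|name|class` headers
(the APD3 database convention). Each CDS is translated in six frames
(standard code; stops stay in-frame as '*', N-codons as 'X') and every
query is aligned to every frame by exact Smith–Waterman with BLOSUM62
and affine gaps (open 11, extend 1: a gap of length g costs 11 + g), a
numba-compiled Gotoh DP with a deterministic traceback (earliest best
cell; match state preferred). Running the full DP instead of a seeded
heuristic keeps scores deterministic and oracle-testable; at gene-set
scale this is cheap. Significance uses the Karlin–Altschul formula with
gapped-BLOSUM62 constants λ = 0.267, K = 0.041:

    bits = (λS − ln K)/ln 2,    E = m·n·2^(−bits)

with m the query length and n the total translated database length. No
edge-effect or finite-size corrections are applied, so E-values deviate
from NCBI BLAST's numerically; the screen depends on thresholds, not on
matching BLAST digits. Filters: E ≤ 1e−5 and query alignment ratio
(aligned query span / query length) ≥ 0.5. The ratio is span coverage,
not identity. Redundancy removal keeps one best hit per gene (lowest
E-value, ties by higher identity then lower query id): the catalog is a
per-gene tally. Genes are renamed class + serial, serials running in
(chromosome, start) order for placed genes then gene id for unplaced
ones — dense and deterministic across reruns. Frames containing stops
inside the aligned span are allowed; the scoring and filters decide.

Not attempted: mature-peptide boundary prediction, signal-peptide
cleavage, activity prediction, pathway enrichment.

## Expression

TPM_i = 10⁶ · (c_i/l_i) / Σ_j (c_j/l_j), with effective length l_i taken
as CDS length (no fragment-length correction — the expected-count
machinery of full quantifiers is out of scope). Per-tissue TPM sums to
exactly 10⁶ whenever any count is nonzero; an all-zero tissue yields all
zeros, not an error. "Detected" means TPM strictly greater than the
threshold, default 0. Top-N ranks descending with name-ascending
tie-breaks and prints two decimals.

## Synthetic studies

The generator emulates the inputs of a chromosome-level fish-genome
project with recorded ground truth:

* **Genome**: i.i.d. bases at 41.4 % GC (the giant-grouper genome-wide
  value), default 2 chromosomes. No repeats, no heterozygosity.
* **Planted genes**: ATG + 5–15 random sense codons + a uniform-random
  synonymous back-translation of a point-mutated query peptide
  (substitution rate default 0.05) + padding + stop, written into
  non-overlapping genome intervals on a random strand; decoys are random
  sense codons with no query-derived segment. Codon usage is uniform —
  the screen does not model it.
* **Fragmentation** partitions chromosomes at random breakpoints that
  avoid gene interiors and keep every scaffold ≥ `min_length` (default
  500 bp, so each scaffold can carry flank-length markers);
  orientation flips with probability 0.5; scaffold ids are shuffled so
  lexicographic order carries no layout information.
* **Markers**: cM is a fixed linear function of true chromosomal
  position (1 cM / 250 kb) plus optional uniform jitter — the study this
  emulates borrowed an external map rather than modelling recombination;
  flanks (default 40 bp) are the true genomic context so exact matching
  relocates them.
* **Reads**: single-end, uniform starts, random strand, i.i.d.
  substitution errors only (no indels); read count =
  round(coverage × genome length / read length); FASTQ quality constant
  'I'.
* **Counts**: multinomial per tissue with probability ∝ abundance ×
  effective length; column totals equal the library size exactly.
* All generators take an explicit seed, default 17.

Passing the recovery suites therefore shows the estimators are correct
under their own assumptions (clean substitution noise, unique flanks,
linear maps, uniform coverage); it does not demonstrate robustness to
repeats, indels, chimeric scaffolds, heterozygosity, or map errors
beyond the jitter tested.

## Problem sizes used in tests and acceptance runs

Chosen as the smallest sizes at which each property is meaningfully
exercised: genome-size recovery on a 200 kb genome at 30× error-free
coverage; anchoring recovery on 2 linkage groups × 20 scaffolds × 3
noiseless markers over 10 seeds; screen recovery on 8 planted genes + 15
decoys per seed over 10 seeds at 5 % substitution; the jittered-map
tolerance check at ~500 kb scaffolds, the realistic resolution scale for
a 1 cM / 250 kb map (±0.5 cM noise cannot resolve 20 kb scaffolds, whose
spacing is 0.08 cM). Oracle sweeps use Biopython's exhaustive local
aligner, brute-force dictionary k-mer counts, a cumulative-scan Nx, a
literal codon table, and a two-pass TPM computation.

## Known limitations

* In-memory k-mer counting only; no disk-backed structures.
* E-values are formula-exact but uncorrected; do not compare digits with
  BLAST output.
* The anchoring never splits chimeric scaffolds; conflicts exclude them.
* Effective length = CDS length; TPM from isoform-aware quantifiers will
  differ.
* The published genome-scale catalog counts (254 AMP genes, 34 classes,
  228 placed) depend on the full sequencing data and annotation and are
  outside what the synthetic suites reproduce; the package reproduces
  the published arithmetic and the algorithmic behaviour, not those
  dataset-bound tallies.
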