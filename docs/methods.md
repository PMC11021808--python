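# Methods

This note documents the algorithms, the default parameters and the
reasoning behind them, what the synthetic benchmark does and does not
show, and the numerical conventions that make the engine deterministic.

## Search model

The engine is a filter-then-verify homology search. The *filter* is
seed-and-vote: exact k-mer matches between database windows and a
query-side index vote on candidate alignment positions, and only
well-supported positions are verified. The *verify* step is banded local
alignment with affine gaps, followed by Karlin–Altschul statistics.

### Query-side k-mer index

The 20 canonical residues are encoded 0–19 (alphabetical); every ambiguity
or non-standard code (B, J, Z, X, U, O, `*`) collapses to a single
"excluded" ordinal. A k-mer's key is its base-20 positional code, so the
key space is exactly 20^k and the table is a CSR layout (offsets +
postings) addressed in constant time. Windows containing a masked or
excluded residue produce no posting. Seeds are exact matches only — no
neighbourhood words as in BLASTP's T-threshold seeding. Sensitivity is
recovered by the small word size (k = 4 default, 2–7 supported) and by the
vote threshold rather than by seed enumeration: at k = 4 two homologous
sequences of typical length share many identical words even at 30–40%
divergence, and each shared word is an independent chance to vote.

### Diagonal voting

For a database window at subject position j matching a query posting at
position i, the hit lies on diagonal d = j − i. Votes accumulate in a
sparse table keyed by (query, subject, ⌊d / w⌋) with bin width w = 16; the
accumulator also tracks, per exact diagonal, the hit count and the
min/max subject positions, so a promoted candidate carries its modal
diagonal (tie → smallest) and seed span. Memory therefore scales with the
number of hits, not with query × subject lengths.

A bucket is promoted when its votes reach the threshold P0 (promotion is
≥, so P0 = 1 keeps single hits — the most sensitive and slowest mode;
the default is 2, which suppresses the large population of single
chance hits between unrelated sequences). Buckets in consecutive bins of
the same pair are merged before thresholding (votes summed, modal diagonal
recomputed) so an HSP straddling a bin boundary is neither split nor lost;
`--no-merge-adjacent` disables this. Candidate promotion is monotone:
the candidate set at P0+1 is always a subset of the set at P0.

The bin width trades indel tolerance against filter specificity: w = 16
tolerates net indel drift of about ±16 residues within one bucket, which
matches the default alignment band half-width (see below) so that any
candidate the filter proposes can actually be resolved inside the band.

### Banded alignment

Each candidate is resolved by Gotoh three-matrix local alignment restricted
to diagonals within ±band_width (default 16) of the candidate's modal
diagonal, i.e. O(band · subject_span) time and memory instead of O(m·n).
Scoring is BLOSUM62 (taken from Biopython's substitution-matrix collection
and re-indexed onto the internal alphabet, with the excluded ordinal
scoring through the X column) with gap open 11 and extend 1, the BLASTP
defaults — a deliberate convention choice, since score comparability with
other engines is limited to ranking anyway. A gap of length L costs
11 + L·1.

Tie-breaking is fully deterministic: traceback prefers diagonal, then
gap-in-subject, then gap-in-query, and closes a gap rather than extending
it when both explain the cell; among equal-scoring end cells the smallest
subject position wins, then the smallest query position. An unbanded
implementation with the identical contract (`reference_smith_waterman`)
serves as the oracle: with a band covering the whole matrix the two agree
exactly, and widening the band can never decrease the score.

The engine computes a score-only banded pass first and runs the
full traceback only when the score can pass the E-value cutoff; the
threshold is the exact inversion of the E-value formula, so the prefilter
never changes the reported hit set. Multiple candidates of one
(query, subject) pair may yield multiple HSPs; HSPs whose subject spans
overlap by ≥ 50% of the shorter span are deduplicated keeping the higher
score.

### Statistics and reporting

bits = (λ·raw − ln K)/ln 2 and E = m·n·2^(−bits) with the gapped BLOSUM62
11/1 constants λ = 0.267, K = 0.041 held as configuration, not estimated.
m is the query length and n the total residue count of the full database,
fixed in a metadata pass before any batch is scanned — so E-values are
batch-invariant. No effective-length (edge) correction is applied; this is
the plain Karlin–Altschul form and differs from BLASTP's corrected
statistics, mildly inflating E for short sequences. Hits pass an E ≤ 10
cutoff by default, are grouped by query in input order, sorted within a
query by (E, −bits, subject id, coordinates), and capped at 500 distinct
subjects per query. Output is BLAST outfmt-6 with 1-based inclusive
coordinates (internally everything is 0-based half-open).

### Masking

Database sequences (and optionally queries) are soft-masked before seeding
with a tandem-repeat model: a hidden background state versus repeat states
of period p = 1..50 with a geometric period prior (decay 0.9), transition
probability into repeat 0.005, out of repeat 0.05 — the parameter values
published with the tantan masker. The emission odds that position i
repeats the residue p back are exp(λ_u · S(a, b)) with the ungapped
BLOSUM62 λ_u = 0.3176. The per-position repeat posterior is computed by
the full forward–backward recursion; a forward-only filter was evaluated
and rejected because it leaves the ramp-up positions of a repeat unmasked
(a 30-residue homopolymer came out only ~73% masked, versus 90–97% with
smoothing). Positions with posterior ≥ 0.9 are excluded from seeding but
stay alignable (soft mask), so alignments still extend through repeats.
Masking never changes residues, is idempotent, and is monotone in the
threshold. Typical i.i.d.-uniform sequence is essentially untouched
(≈ 0.02% of positions).

## Pipeline and determinism

The database is split greedily in input order into batches of at most
`batch_budget` residues (default 10^8; an oversized single record gets its
own batch rather than being split, avoiding cross-batch HSP stitching).
Per batch, the stages mask → scan/vote/promote → align run under a
producer–consumer scheduler with a configurable worker pool: different
batches may occupy different stages concurrently, each batch enters each
stage exactly once, a stage failure cancels that batch's downstream stages
and surfaces the earliest batch's error, and a final merge re-establishes
batch order. Because subject identifiers are global database indices,
per-subject vote buckets are local to their batch and candidates are
identical however the database is partitioned; combined with the global-n
E-values and the total ranking order, output is byte-identical across any
(batch budget, worker count) combination — a property the acceptance suite
checks literally. The scan honours a single-pass contract (each database
residue consumed exactly once per search), instrumentable via
`ScanCounter`.

The compute kernels are a vectorized numpy scan (window coding, postings
expansion, grouped accumulation) and numba-compiled banded DP loops; the
thread pool covers the alignment stage. This is a faithful CPU realisation
of a device/host split — bulk data-parallel seeding/voting versus
logic-heavy alignment — without any GPU dependency.

## Synthetic benchmark

`seedvote.synthetic` generates decoy proteomes with i.i.d. residues
(uniform over the 20 canonical residues by default) and lengths uniform on
100–500, and plants homologs by per-position substitution (replacement
uniform over the other 19 residues) with optional geometric-length indels.
Uniform replacement is deliberately conservative for the seeder: real
substitution processes preserve k-mers more than uniform replacement does,
and natural composition bias makes chance seeds more, not less, frequent —
so the planted-homolog sensitivity measured here is a pessimistic bound
with respect to the mutation model, while the decoy background is milder
than real low-complexity-rich databases (which is why masking is always
exercised separately). What these fixtures do not emulate: domain
architecture, repeats and compositional bias in homologs, realistic length
distributions, or deep phylogenetic divergence structure. Passing the
benchmark therefore demonstrates the engine's filtering and alignment
mechanics, not field sensitivity on natural proteins.

Problem sizes in the shipped tests and the acceptance script — 100-sequence
self-search, 200 planted homologs among 2,000 decoys (~0.66 M database
residues), 200 oracle pairs of length ≤ 80 — were chosen to exercise every
code path, including multi-batch streaming and the most sensitive P0 = 1
mode where every chance k-mer hit is aligned, while remaining comfortable
on a single CPU core.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| k | 4 | seed word length (2–7); smaller = more sensitive |
| P0 (`--votes`) | 2 | min votes per diagonal bin; 1 = slowest/most sensitive |
| bin width | 16 | diagonal bin granularity (residues) |
| band width | 16 | alignment band half-width around the candidate diagonal |
| matrix / gaps | BLOSUM62, 11/1 | BLASTP-convention scoring |
| λ, K | 0.267, 0.041 | gapped Karlin–Altschul constants for BLOSUM62 11/1 |
| E cutoff | 10 | report threshold |
| max targets | 500 | distinct subjects per query |
| batch budget | 10^8 | residues per database batch |
| masking | on (database) | tantan-style, period ≤ 50, posterior ≥ 0.9 |

## Known limitations

- Exact-seed filtering with small k is quadratic in the number of chance
  word matches at P0 = 1; on very large query sets against large databases
  the alignment stage dominates, as expected for the most sensitive mode.
- E-values use raw search-space lengths (no edge correction) and fixed
  λ/K; they rank correctly but are not numerically interchangeable with
  BLASTP E-values.
- One HSP per candidate; alternative sub-optimal alignments inside the same
  band are not enumerated.
- Only the BLOSUM62 matrix and the tabular output dialect are built in.
- Protein only: no translated searches, spaced seeds, or profile modes.
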