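# seedvote

Seed-and-vote protein homology search at desk scale.

`seedvote` searches a set of query proteins against a protein database and
reports local alignments in BLAST tabular format, the way BLASTP would — but
it is organised around three ideas that make many-query searches against
large databases cheap:

1. **Index the queries, not the database.** A k-mer table (default k = 4)
   is built over the query set only, so its size depends on the queries
   alone and stays constant however large the database grows. No database
   index is ever built or stored.
2. **Stream the database once, in batches.** The database is split into
   memory-budgeted sub-databases. Each batch is traversed in a single pass:
   every (unmasked, ambiguity-free) k-mer window is looked up in the query
   table, and each hit casts a *vote* on the diagonal bin of its
   (query, subject) pair, where the diagonal is
   d = subject_pos − query_pos and bins are ⌊d / w⌋ with bin width w = 16.
   Ungapped homology concentrates votes on one diagonal; small indels
   drift it by a few positions, which the binning absorbs.
3. **Align only what the votes support.** A bin with at least P0 votes
   (default 2; P0 = 1 is the slowest, most sensitive mode — every single
   k-mer hit is examined) becomes an HSP candidate, resolved by banded
   affine-gap Smith–Waterman (Gotoh) restricted to
   |d − d_candidate| ≤ 16, scored with BLOSUM62 and gap penalties 11/1.

Raw scores S are converted to bit scores S′ = (λS − ln K)/ln 2 with the
gapped BLOSUM62 constants (λ = 0.267, K = 0.041) and to E-values
E = m·n·2^(−S′), where n is the residue count of the *whole* database, so
E-values — and the entire output, byte for byte — are independent of the
batch budget and the worker count.

Database sequences are soft-masked before seeding with a tandem-repeat
model in the spirit of tantan (a background/repeat hidden process with a
geometric prior over repeat periods; positions whose posterior repeat
probability reaches 0.9 are excluded from seeding but remain alignable).

The package is aimed at people who want a transparent, fully testable
implementation of the seed-and-vote search strategy: every stage (I/O,
masking, indexing, voting, alignment, statistics) is an importable module
with an explicit contract, and the banded aligner and the vectorized
scanner ship with independent brute-force oracles in the test suite.

## Worked example

Generate a small synthetic proteome, plant one diverged homolog (30%
substitution) per sequence, and search the parents against both:

```bash
seedvote fixtures proteome -n 5 --min-length 120 --max-length 200 --seed 42 --out proteins.fasta
seedvote fixtures homologs --parents proteins.fasta --substitution-rate 0.3 --seed 7 --out homologs.fasta
cat proteins.fasta homologs.fasta > db.fasta
seedvote search --query proteins.fasta --db db.fasta --out hits.tsv --votes 1
cat hits.tsv
```

Output (BLAST outfmt-6: qseqid, sseqid, pident, length, mismatch, gapopen,
qstart, qend, sstart, send, evalue, bitscore):

```
syn_0001	syn_0001	100.00	127	0	0	1	127	1	127	2.2e-79	278.9
syn_0001	syn_0001_hom	64.29	126	45	0	2	127	2	127	2.4e-41	152.5
syn_0002	syn_0002	100.00	182	0	0	1	182	1	182	2.4e-119	412.1
syn_0002	syn_0002_hom	70.88	182	53	0	1	182	1	182	3.4e-73	258.8
syn_0003	syn_0003	100.00	155	0	0	1	155	1	155	9.2e-104	360.1
syn_0003	syn_0003_hom	72.90	155	42	0	1	155	1	155	1.2e-66	236.9
syn_0004	syn_0004	100.00	158	0	0	1	158	1	158	3.5e-103	358.2
syn_0004	syn_0004_hom	68.79	157	49	0	2	158	2	158	2e-61	219.5
syn_0005	syn_0005	100.00	146	0	0	1	146	1	146	8.9e-93	323.6
syn_0005	syn_0005_hom	71.53	144	41	0	2	145	2	145	2.5e-58	209.1
```

Each query finds itself (100% identity, E ≈ 10⁻⁸⁰…10⁻¹²⁰) and its planted
homolog (~65–73% identity: 30% substitution, full-length coverage, E still
far below 1), and nothing else at this E-value cutoff. Identities above the
expected 70% arise because some substitutions are conservative and the
local alignment may trim a noisy end column.

The same search is available as a library call:

```python
from seedvote import SearchConfig, run_search
hits, stats = run_search("proteins.fasta", "db.fasta",
                         SearchConfig(vote_threshold=1), out="hits.tsv")
```

`stats` carries the per-stage counters (windows scanned, votes, candidate
bins, alignments, hits) that the pipeline also logs to standard error.

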