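# Methods

`orfanscan` implements a discovery procedure for RNA virus segments whose
encoded proteins have no detectable similarity to anything annotated
(ORFans).  Because similarity search cannot vouch for them, the pipeline
substitutes three orthogonal lines of evidence: absence of a database hit
combined with coding potential, stranded read support on *both* strands of
the contig (the hallmark of RNA replication through a complementary
template), and — for bisegmented viruses — co-segregation of an RdRP
segment (RNA1) with a companion segment (RNA2).

## Stage 1 — ORFan candidate screen

A contig is a candidate iff

1. its id is absent from the similarity-search hit set (BLAST/DIAMOND
   tabular, e-value column 11; hits at `evalue <= evalue_max`, default
   `1e-3`, disqualify a contig — the upstream search's own threshold is
   unknown, so it is exposed in config);
2. its length is **strictly** greater than `min_len = 1000` nt (a common
   lower bound for mycovirus genomic segments);
3. some ORF encodes a protein **strictly** heavier than
   `min_mass = 15 kDa`.

ORF calling scans all six frames.  A run of stop-free codons yields one ORF
from its first ATG; a run open at the contig terminus with no ATG is still
reported (`complete5=False`) because assemblies truncate 5' ends and the
mass filter must see those proteins.  Codons containing N never translate
and terminate the run without a stop (`complete3=False`).  Coordinates are
0-based half-open on the plus strand internally (including the stop codon
when present) and 1-based in reports.  Protein mass uses the standard
*average* residue masses plus one water (18.0153 Da); `X` weighs the mean
of the twenty residues.  Average rather than monoisotopic mass matches
common protein-parameter calculators at these protein sizes.

## Stage 2 — strand profiling

Each mapped, primary alignment contributes one count.  Under
`fr_firststrand` (dUTP/TruSeq-stranded chemistry, the default) a single-end
or first-in-pair read aligned forward originates from RNA antisense to the
contig and increments `minus`; aligned reverse increments `plus`;
second-in-pair reads follow the inverted rule; `fr_secondstrand` flips
everything.  The protocol is an explicit setting because a misdeclared
protocol silently swaps the biology.

The keep rule discards contigs with fewer than `min_each = 1` reads on
either strand (sense-only = transcript-like).  Polarity is
`minus_dominant`/`plus_dominant` when one strand exceeds `dominance_ratio`
(default 1.0) times the other, `balanced` otherwise, and `insufficient`
below `min_total = 10` reads; `min_total` and `dominance_ratio` are
robustness additions for low-coverage contigs, beyond the literal
both-strand rule.  In the full pipeline the keep rule is applied to
tallies pooled across libraries; per-library profiles are reported
unchanged.

## Stage 3 — identity and clades

Pairwise identity over an alignment is
`100 * matches / (columns where both rows are non-gap)`; a pair with no
co-occupied columns scores 0 with a warning.  The denominator convention
is a deliberate, stated choice — published identity matrices rarely say
which they used.  When no curated MSA is supplied, each pair is globally
aligned (Needleman–Wunsch/Gotoh affine gaps via Biopython, BLOSUM62,
gap of length *k* costing `11 + k`).  Clades are connected components of
the graph with an edge at identity >= `threshold_pct` (single linkage);
the default 15% sits between the observed inter-group (<10%) and
intra-group identities of the target virus group.  Labels are ordered by
clade size, then smallest member id.

Caveat: forced end-to-end alignment of unrelated proteins yields nonzero
background identity (often 10–20%), so clading raw, unaligned random
proteins at the default threshold is not meaningful; for real analyses
supply the curated MSA.

## Stage 4 — palm motifs and catalytic triads

Anchor columns for palm motifs A (conserved D), B (two conserved G) and C
(central catalytic D) are found by per-column conservation over all rows
(gaps count against), requiring frequency >= `min_frac = 0.7`, motif-B
glycines at most 3 columns apart (adjacent preferred), and spacings
`A->B >= 20` and `B->C >= 5` columns, which reflect typical palm-domain
layout.  Among valid arrangements the most D-conserved motif-C column wins
(ties toward the smallest index).  The structure-guided anchoring used to
curate real alignments is out of scope; explicit anchor columns can be
passed instead.  The triad is the residue triple at columns
`(C-1, C, C+1)`; `GDD` is canonical, `SDD`/`GDN` known rare variants (the
catalog is configurable), anything else complete is novel, and a
gap-containing triad is incomplete and excluded from the tally.

## Stage 5 — segment association

Three evidence streams over candidate pairs, combined by an explicit rule
(the narrative reasoning of segment-association arguments made
reproducible):

* **STRONG** — ungapped terminal comparison of the plus-sense sequences:
  at most 2 mismatches in the first `k = 20` nt *and* at most 2 in the
  last `k`.  `k = 20` matches the resolution at which conserved termini
  were established for the founding virus of this group (one mismatch in
  the first twenty nucleotides).
* **MODERATE** — exact qPCR co-occurrence (presence = Ct <= 38, blank or
  missing = absent) with at least 2 shared positive isolates.
* **WEAK** — Pearson r >= 0.9 between `log10(count+1)` per-library read
  counts over >= 3 informative libraries (libraries where both segments
  have zero reads are dropped; the log is used because counts span orders
  of magnitude).

`associated` requires STRONG, or MODERATE and WEAK together.  Every
threshold is configurable and echoed into the report.  The two termini are
reported separately because "conserved ends" need not mean both ends
equally.

## Synthetic data

The generator emulates exactly the discriminating structure the pipeline
assumes: host contigs carry a strong fabricated hit and sense-only reads;
each virus contributes an RNA1 (planted single ATG-initiated ORF > 15 kDa
containing D, GG and a requested triad in order, with an in-frame stop
planted immediately upstream of the initiator so a six-frame scan reports
exactly the planted ORF) and an RNA2 (same construction without motifs),
the pair sharing identical first/last 20 nt; each virus infects a
pairwise-distinct subset of >= 2 samples (distinct infection patterns are
what make cross-virus pairs distinguishable in an isolate panel, and the
generator guarantees them); read counts per (segment, sample) share a
lognormal depth factor within a virus so true pairs correlate; reads are
150 nt single-end (paired mode available), Poisson depth, Bernoulli strand
of origin, uniform substitution errors (default 0.5%).  Ct values are
Uniform(20, 30) where present, blank otherwise.

What it does **not** model: indels and quality-dependent errors, chimeras,
assembly artefacts, multi-mapping, host antisense transcription (available
as a hard-negative option via `host_plus_fraction`), and real protein
homology — synthetic "clades" are random proteins.  Passing tests on this
generator therefore demonstrate correctness of the decision machinery
under its stated assumptions, not performance on real libraries.

A companion MSA generator plants motif columns in random alignments and
applies per-column substitution noise *including at motif columns*,
recording the emitted per-row triads as truth; anchor recovery checks the
conservation heuristic while triad recovery checks extraction fidelity.

## Numerical and design choices

* Strict inequalities for the length and mass filters, as specified.
* Ct parsing accepts decimal commas (lab exports) when the delimiter is
  tab or semicolon; blank = missing; missing = absent at binarisation.
* SAM consumption is text-only and minimal (flag, read name, reference
  name): orientation is the only alignment evidence used, and headerless
  SAM must parse, with truncated records reported by line number.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator`; bundles are byte-reproducible.
* Determinism of reports: sorted ids everywhere, JSON with sorted keys,
  no timestamps.
* Degenerate inputs: empty contig set gives an empty successful report;
  an all-below-threshold identity matrix gives all-singleton clades; a
  conservation-free MSA gives a no-anchor result rather than an error.

## Problem sizes in tests and acceptance runs

Test and acceptance simulations use deliberately compact conditions chosen
to exercise every code path with comfortable statistical margins: bundles
of 4 host contigs + 3 viruses over 4 samples at mean depth 150 (noise-free,
plus fraction 0.5) for end-to-end recovery across 20 seeds; depth 1000–2000
for strand-concentration checks; 24-row, 130-column MSAs at 90% per-column
motif conservation for triad recovery (at 24 rows, the probability of a
planted column dropping below the 0.7 detection threshold is negligible);
200 random 300-nt sequences against the brute-force six-frame oracle; 100
random matrices against the BFS component oracle.
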