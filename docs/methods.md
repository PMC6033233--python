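# Methods

## Problem and scope

Designing CRISPR guides at scale has two computational halves: (i) find
every candidate target (protospacer + PAM) in a reference sequence, and
(ii) for each candidate, enumerate all genomic sites within a mismatch
budget *k* — experimentally active off-targets have been observed at up to
six mismatches — and summarise them into specificity, activity, and
design-rule metrics.  guidescout implements both halves as a reusable
library with a thin command-line front end.  Runtime benchmarking against
other tools, and reproduction of published genome-scale library designs,
are out of scope; correctness is established against in-package oracles on
synthetic data.

## Target model

An enzyme is a set of equal-length IUPAC PAM patterns, a PAM side, and a
protospacer length.  Registered enzymes: SpCas9 `NGG` (3′ PAM), SpCas9
`NGG`/`NAG`, and Cpf1 `TTTN` (5′ PAM), all with 20-base protospacers.  A
target site is any position, on either strand, where a PAM pattern
matches and the full site lies inside the contig.  Coordinates are
0-based, half-open, on the forward strand everywhere; protospacer and PAM
strings are reported in guide orientation.  A position/strand matching
several patterns of a multi-PAM enzyme is emitted once, with the first
matching pattern's bases recorded (the concrete PAM is needed later for
CFD's PAM penalty).  Sites containing non-ACGT bases cannot be 2-bit
encoded and are skipped with a tally; soft-masked (lower-case) bases are
uppercased and used by default, with an opt-in flag to skip them.  Ten
bases of flanking context are captured on each side of the site when
available — enough for the 30-mer and 35-mer on-target windows — and
candidates too close to a contig edge simply carry no context and receive
no-score markers from context-dependent models.

## Encoding

Bases pack 2 bits each (A=00, C=01, G=10, T=11 — alphabetical; arbitrary
but fixed and stamped in the database header version).  A target word is

    [suffix bases | PAM bases | 16-bit count],  most significant bits first,

where the *suffix* is the protospacer minus the first *p* bases (the bin
prefix, implicit in the bin).  With sites capped at 24 bases, sequence
bits plus the count always fit in 64; recovering the prefix from the bin
is what buys the extra *p* bases.  Counts saturate at 65 535 rather than
wrap or error — the search's occurrence limit (default 2000) makes exact
counts beyond that irrelevant — and a bin-level flag records saturation.
Positions pack as 24-bit contig index / 39-bit offset / strand bit,
supporting 16.7 M contigs and 549 Gb offsets.

Mismatch counting is bit-parallel: XOR two words, fold each 2-bit slot to
one indicator bit (`x | x>>1`, masked to the low bit per slot), AND with a
mask that covers only protospacer-suffix slots (so PAM bases and the count
field can never contribute), popcount.  The same three vector operations
run over whole bins as numpy `uint64` arrays via `np.bitwise_count`.

## Database

Layout: magic `CRDB`, format version, a pointer to a JSON header
(enzyme, prefix length, contig table, per-bin offset/size/CRC32 index,
summary counts), and one independently deflate-compressed block per
non-empty bin.  Bin payloads are columnar — words, per-entry position
counts, then all positions — so the reader materialises numpy arrays
without a per-entry loop.  Entries are sorted by sequence bits; duplicate
sequences collapse to one word whose count tallies the genomic
occurrences, with every position retained.

Build is two-pass with bounded memory: pass 1 streams discovered sites as
(prefix code, word, position) triples into 256 disk buckets keyed by the
first four prefix bases; pass 2 loads one bucket at a time, sorts,
deduplicates, and writes bins in ascending prefix order.  CRC32 checksums
catch corrupted blocks at read time with an error naming the bin.

Defaults and why: prefix length *p* = 7 (4⁷ = 16 384 bins balances bin
size against index size; it is settable at build time, and databases built
at different *p* over the same genome contain identical sequence→position
maps).  Bins with more than 50 000 entries get a nested offset table keyed
on the next four bases; the threshold is a free parameter and the nested
table is equivalent to (and tested against) binary search on the sorted
entries.

## Search

For each guide, a bin is *planned* iff the Hamming distance between the
guide's first *p* protospacer bases and the bin prefix is ≤ *k*.  Because
prefix mismatches lower-bound total mismatches, no hit can hide in an
unplanned bin (the test suite asserts exactness, not just recall).  The
union of planned bins is traversed in ascending prefix order, each bin
decompressed once regardless of how many guides visit it.  When the plan
covers more than 95% of *non-empty* bins — common with large guide sets or
high *k* — the database is instead scanned linearly to avoid seek
overhead.  The 95% rule is evaluated over non-empty bins because empty
prefixes cost nothing either way; forced-linear and forced-selective modes
are required (and tested) to return identical results, including overflow
flags, which a fixed traversal order makes deterministic.

The off-target limit counts genomic *occurrences* (the sum of count
fields), not distinct sequences — repeats are what make a guide
unusable — and a guide whose tally exceeds the limit (default 2000,
matching the default mismatch ceiling of 4 used by `discover`) is flagged
`OVERFLOW`, stops accumulating hits, and is excluded from off-target
scoring downstream.  A guide identical to its own genomic site keeps that
site as a 0-mismatch hit at search time; the scoring layer removes exactly
one occurrence matching the candidate's own coordinates (falling back to
one occurrence of the identical-sequence hit when coordinates are not
carried), because otherwise every genomic candidate would be capped at an
Hsu score of 50 by its self-hit.  A flag restores the self-hit for users
scoring guides against *other* references.

`brute_force_search` ships in the package as the ground-truth
implementation: it compares every discovered site to every guide as
character arrays, sharing no code with the codec or the binned traversal,
and is the oracle in the exactness tests and the acceptance script.

## Scoring

**Hsu 2013 aggregate** (0–100, higher = more specific).  A single hit with
mismatched positions *P* (1 = PAM-distal) scores
`100 · Π_{p∈P}(1 − M[p]) · D · 1/|P|²`, where `D = 1/(((19 − d̄)/19)·4 + 1)`
and d̄ is the mean pairwise distance between mismatch positions (D = 1 for
fewer than two mismatches).  The guide aggregate is
`100·100 / (100 + Σ)`, the sum running over every genomic occurrence of
every non-self hit — so one perfect off-target gives exactly 50, and each
additional hit strictly decreases the score.  The position weights M ship
as a transcription of the published values.

**CFD** (0–1 per hit).  Product over mismatched positions of a penalty
keyed by (position, guide RNA base, target-strand DNA base) — a
Watson-Crick pair is a match and implicitly scores 1 — times a penalty on
the last two PAM bases (GG = 1, AG the strongest alternative).  Reported
per guide as the maximum over non-self hits (worst case), 0 with no hits.
PAM tails absent from the table penalise to 0 with a warning.  Both Hsu
and CFD are defined for 20-mer guides with a 3-base 3′ PAM; Cpf1
candidates receive no-score markers, as the underlying models are
Cas9-specific.

**On-target models.**  Both bundled activity models are positional-weight
sums: indicator terms for specific mono- and dinucleotides at window
positions, GC-content terms over the protospacer, an intercept, and an
output transform — logistic for the 30-mer rule-set-1 shape (4 bases
upstream, protospacer, PAM, 3 downstream), identity for the 35-mer
CRISPRScan shape.  Evaluation is a pure sum; a model declares its window
and returns a no-score marker when the stored context cannot supply it.

**Coefficient provenance.**  The Hsu weight vector and the CFD PAM-tail
table are transcriptions.  The CFD per-position mismatch table and both
on-target coefficient sets are *synthetic stand-ins*: files with the
published models' exact structure (keys, ranges, window geometry,
transforms) but seeded placeholder values, clearly labelled in filename
and header.  This keeps every code path exercised end-to-end while being
honest that absolute CFD/on-target values are not the published ones;
transcriptions drop in through the documented TSV schema without code
changes.  Correctness of the machinery is established against small
hand-computed tables, never against the bundled transcriptions.

**Flags.**  GC fraction of the protospacer strictly above 0.75 / below
0.25 raises `gc_high`/`gc_low`; a `TTTT` tract (which can terminate pol
III transcription) raises `polyT`.  The thresholds are this package's
choices — the flags are standard but published cutoffs vary.  A
`reciprocal` flag marks candidates with a hit (other than their own site)
inside the region of interest, the configuration that risks deleting the
intervening sequence; the region defaults to the per-contig span of the
queried candidates and can be given explicitly as BED.

**Rank aggregation.**  Each metric ranks all candidates (best = 1, mean
rank on ties, missing scores last — this keeps the median defined for
partially scored guides).  Hsu and the on-target models rank
higher-is-better; CFD-max ranks lower-is-better since it measures risk.
The median of the per-metric ranks orders everything; the best `top_n`
(default 1000) are re-ordered by the Schulze method with each metric's
ranking as one ballot: pairwise preference counts, widest-path strengths
by Floyd-Warshall on the max-min semiring, candidates sorted by path
victories with ties broken by mean ballot rank then input order.  The
implementation is tested against exhaustive simple-path enumeration on
elections of up to seven candidates.

## Synthetic data

`fixtures.synth_genome` draws i.i.d. bases at a requested GC fraction;
`fixtures.plant_offtargets` overwrites non-overlapping slots with copies
of a guide's site mutated at exactly *d* protospacer positions (PAM kept),
on random strands, recording a truth table.  This emulates the one thing
the search engine cares about — sites at known mismatch distances in
arbitrary background — and deliberately omits repeat structure, GC
heterogeneity, soft-masking, and variation found in real genomes, so
passing tests demonstrate algorithmic exactness, not performance on
repetitive references.  Because random background can contain incidental
near-matches, truth tables are asserted as supersets (every plant
recovered at its exact *d*); exact-set equality is only ever asserted
against the brute-force oracle.

## Numerical and determinism choices

All scores are pure functions of strings and small tables; no floating
point accumulates across candidates, and ties break by fixed rules
(documented above), so identical inputs give byte-identical output files
— floats are written at fixed precision (Hsu 4 d.p., CFD and on-target
6 d.p.) and the committed golden tables pin the whole pipeline.  All
randomness (genome synthesis, planting, random guides) flows through
seeded numpy generators.

Problem sizes used by the default test suite and the acceptance script —
genomes of 100 kb–1 Mb, guide sets of 1–1000, k ∈ {0..6}, ~2400-copy
repeats for overflow — were chosen so the whole battery runs in a couple
of minutes on one CPU while still crossing every algorithmic regime
(selective and linear traversal, sub-indexed bins, saturation-free
counts, overflow).

## Known limitations

- No bulge/indel off-targets and no gapped alignment; mismatches only.
- Sites are capped at 24 bases (plus prefix); ambiguity codes in the
  reference are skipped, not enumerated.
- Bundled CFD-mismatch and on-target coefficients are synthetic
  stand-ins (see above); absolute values of those scores are not
  comparable to published ones until transcriptions are substituted.
- The database is write-once; no incremental updates or concurrent
  writers, and per-contig offsets are limited to 39 bits.
- Occurrence counts saturate at 65 535; guides that common are far past
  the overflow limit anyway.
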