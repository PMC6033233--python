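# guidescout

Fast, self-contained CRISPR guide design for large target sets: discover
every protospacer+PAM site in an arbitrary FASTA, compile them into a
sorted, prefix-binned, block-compressed binary database, enumerate
off-targets for thousands of candidate guides at user-chosen mismatch
thresholds, and score/flag/rank the candidates into a flat text table.

It is built for people running genome-wide knockout libraries, noncoding
deletion scans, or guide design against non-model genomes and engineered
sequences — workloads where web tools that process one locus at a time, or
aligner-backed pipelines capped at ~3 mismatches, do not scale.  Everything
runs from the command line, reads plain FASTA/BED, and writes TSV.

## How it works

**Database.** For an enzyme (SpCas9 `NGG`, SpCas9 `NGG`/`NAG`, or Cpf1
`TTTN` with a 5′ PAM), every PAM-matching site on both strands is encoded
into one 64-bit word — 2 bits per base for the protospacer suffix and PAM,
plus a 16-bit occurrence count that saturates at 65 535 — followed by one
64-bit word per genomic position (24-bit contig index, 39-bit offset,
strand bit).  Targets sharing their first *p* protospacer bases (default
*p* = 7) land in the same *prefix bin*; bins are sorted, deflate-compressed
independently, and indexed by file offset, with large bins carrying a
nested sub-index on the next four bases.

**Search.** The Hamming distance between a guide's prefix and a bin's
prefix lower-bounds the distance to every target in the bin, so a guide
only visits bins within *k* mismatches of its prefix.  The union of
planned bins over all guides is traversed once, ascending; inside a bin,
mismatches are counted bit-parallel (XOR, fold each 2-bit slot to an
indicator, popcount) with the PAM masked out.  When the plan would touch
more than 95% of non-empty bins, the whole database is scanned linearly
instead; both modes return identical results.  Guides whose accumulated
off-target occurrence tally exceeds a limit (default 2000) are flagged
`OVERFLOW`, dropped from further comparison, and withheld from specificity
scores.  A brute-force reference search ships in the package and the test
suite holds the indexed search exactly equal to it.

**Scoring.** Per guide: the Hsu et al. 2013 aggregate specificity score
(100·100/(100 + Σ single-hit scores), each single hit the product of
per-position penalties (1 − M[p]) damped by the mean pairwise mismatch
distance and the squared mismatch count); the CFD (cutting frequency
determination) score per hit, reported as the worst-case maximum;
positional-weight on-target models in the Doench 2014 (30-mer, logistic)
and CRISPRScan (35-mer, linear) shape; GC/poly-T design flags; reciprocal
off-target flags inside the region of interest; BED annotation; and rank
aggregation — per-metric ranks, their median, and a Schulze (widest-path
Condorcet) re-ranking of the top candidates.

> **Note on coefficients:** the Hsu position weights and the CFD PAM-tail
> penalties ship as transcriptions of the published values.  The CFD
> per-position mismatch table and the two on-target coefficient sets ship
> as clearly labelled *synthetic* stand-ins with the published models'
> exact structure; substitute transcriptions of the original supplements
> via `load_cfd_table(mismatch_path=...)` / `load_models(path=...)` (same
> TSV schema) to reproduce published score values.  All scoring machinery
> is validated against hand-computable tables, so correctness does not
> depend on any particular coefficient file.

## Worked example

```bash
# a deterministic 50 kb two-contig demo genome
python -c "from guidescout.fixtures import synth_genome, write_fasta; \
           write_fasta(synth_genome(seed=11, length=50000, gc=0.45, n_contigs=2), 'demo.fa')"

guidescout index    --fasta demo.fa --enzyme spcas9ngg --output demo.db
guidescout discover --database demo.db --fasta demo.fa \
                    --max-mismatch 4 --include-positions --output demo_discover.tsv
guidescout score    --input demo_discover.tsv --enzyme spcas9ngg \
                    --top-n 50 --output demo_scored.tsv
```

The log (stderr) reports what happened at each step:

```
indexed 5024 sites (0 skipped non-ACGT) into 4276 bins across 2 contig(s)
discovered 5024 candidates; traversal=linear bins_visited=4276 overflowed=0
scored 5024 candidates with metrics ['hsu2013', 'cfd', 'doench2014', 'crisprscan', 'basic', 'rank']
```

(`traversal=linear`: with all 5024 genomic guides queried at k = 4 the bin
plan covers >95% of non-empty bins, so the fallback full scan is used.)
The top of the scored table, sorted by Schulze rank:

```
 contig start                  target  hsu2013      cfd doench2014 crisprscan medianRank  schulzeRank
contig0 22230 ATTTAGCCTTGACGGCATACGGG 100.0000 0.000000   0.821987   0.562080     1344.8            1
contig1 18652 TGTGGGACGTGAAAGAACGCAGG 100.0000 0.000000   0.838172   0.545512     1358.8            2
contig0 12923 GAGTAGCGATGTCCACATTTCGG 100.0000 0.000000   0.815065   0.547821     1356.2            3
```

`hsu2013 = 100` and `cfd = 0` mean no off-target within 4 mismatches
besides the guide's own site (excluded by default); the on-target columns
are the two positional-weight model outputs (higher = more active); the
`medianRank` column is the median of the per-metric ranks over all 5024
candidates and `schulzeRank` orders the top 50 by widest-path victories.
All coordinates are 0-based half-open on the forward strand.

## Layout

```
src/guidescout/
  bitcodec.py    2-bit packing, 64-bit target/position words, popcount mismatches
  enzymes.py     enzyme/PAM definitions, IUPAC matching
  discovery.py   both-strand FASTA scanning, random guide generation
  database.py    prefix-binned block-compressed database build/read
  search.py      bin-planned search, linear fallback, brute-force oracle
  scoring.py     Hsu 2013, CFD, design flags, reciprocal off-targets
  ontarget.py    positional-weight on-target models
  ranking.py     median rank + Schulze aggregation
  annotate.py    BED annotation, TSV writer
  tables.py      discover/score flat-table layer
  fixtures.py    synthetic genomes and planted off-targets
  cli.py         `guidescout index|discover|score|random`
```

See `docs/methods.md` for the scientific details, parameter defaults, and
known limitations.
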