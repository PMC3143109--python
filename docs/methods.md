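# Methods

## Storage model

hitdb stores mapped-read *positions*, not alignments. The unit of
storage is the hit: (chromosome id, 5′ position, strand, aligned length,
weight). This is sufficient for coverage-style analyses — ChIP-Seq peak
calling, DNase hypersensitivity, methylation summaries, RNA-Seq
quantification over known features — which need read locations and
multiplicities but not sequences, qualities, or mismatches. Those
applications are the design target; anything needing per-base evidence
(SNP calling, assembly) is out of scope by construction.

Hits are laid out per chromosome as parallel column files sorted by 5′
position (see `docs/FORMAT.md`). The column layout means projection
queries (positions only, weights only) read only the bytes they need,
and the sorted order supports a sparse block index: one (first-position,
record-offset) entry per 1024 records. A region query binary-searches
the index for the last block starting at or before the region start,
caps the scan at the first block starting after the region end, and
decodes only that record range. The decode count is therefore at most
m + 2B records for m results — bounded overshoot of less than one block
at each end — independent of the store size n. This is the measurable
form of the O(log n + m) query-cost contract, and it is asserted
directly in the tests via `QueryStats.records_decoded` rather than by
timing, which would be hardware-dependent.

### Why B = 1024 records

Index granularity trades index size against scan overshoot. Blocks much
smaller than one disk read buy nothing; blocks much larger inflate the
worst-case scan. 1024 records = 4 kb of the position column is the dense
end of the useful range: it keeps the worst-case overshoot at two blocks
(2048 records ≈ 20 kb across the three columns) while a 64 kb index
still addresses over 8 million records — comfortably more than typical
per-chromosome hit counts — so a server can hold hundreds of experiment
indexes in memory.

## Query semantics

- **Selection is by stored 5′ position, not span overlap.** Hits are
  sorted and indexed by the single 5′ coordinate; a minus-strand hit
  whose covered bases reach into a region but whose 5′ end lies outside
  it is *not* returned. Span-overlap queries are a documented non-goal;
  callers needing them can widen the region by the maximum read length.
- **Intervals are 1-based, inclusive on both ends**, matching SAM, so
  the importer does no coordinate shifting beyond BED's 0-based
  half-open convention.
- **Weight filtering is inclusive** (`weight ≥ minweight`), so a
  threshold of 1.0 keeps uniquely mapped reads under the 1/k convention.
  Comparisons happen at float32 precision, the storage width.
- **Histograms bin by 5′ position and anchor at the region start**: a
  hit at p contributes to the bin starting at
  `start + binwidth·floor((p−start)/binwidth)`. Anchoring at the query
  start makes results independent of any chromosome-origin convention;
  empty bins are omitted. By construction the bin totals conserve
  `count_hits` / `sum_weights` over the same region and filter (weight
  sums accumulate in float64).
- **Unknown chromosomes yield empty results, not errors**: an alignment
  simply has no reads mapped there.
- **Paired queries** select the left- or right-keyed partition; the
  region and strand filter apply to the keyed side. Because every pair
  is stored under both keyings, anchoring on either end is a partition
  choice, not a join.

## Paired-end storage

Each pair is stored twice: once in the `pairedL` partition of its left
end's chromosome (sorted by the left 5′ position) and once in the
`pairedR` partition of its right end's chromosome. "Left" is the end
with the smaller (chromosome id, 5′ position) key, ties broken `+`
first — a total order, so the labelling is deterministic even for
interchromosomal or same-position pairs. The mate's chromosome is
stored explicitly (4 bytes) so interchromosomal pairs round-trip. The
duplication doubles paired storage (20 bytes per record instead of 10)
in exchange for O(log n + m) access from either side; the two
partitions are bijective under anchor/mate swap, which the tests check
exhaustively on synthetic sets.

## Import rules

- 5′ position: leftmost aligned base for forward-strand records,
  `POS + span − 1` for reverse-strand.
- Hit length is the *reference-consuming* span of the alignment, so
  spliced/indel alignments get their genomic extent. Spans over 32767
  (the 15-bit field limit) are skipped and tallied in the import report.
- Weight = 1/k for a read with k alignments: k from the standard NH tag
  when present, otherwise a per-name record count. Consequently the
  total imported weight equals the number of distinct reads — checked as
  a conservation test.
- Mates are joined by read name, cross-checked by mate coordinates;
  orphans are skipped and tallied. Pair weight is 1/(number of pair
  alignments).
- BED input: 0-based half-open converted to 1-based inclusive; the score
  column is taken as the weight when it parses as a finite number > 0
  (BED has no multiplicity concept, so this is the only weight channel).
- Chromosome names map to integer ids through a persisted sidecar
  (`chrommap.tsv`); SAM header order seeds the assignment so re-imports
  and parallel imports of the same reference produce identical stores.

## Determinism and the canonical order

Within a partition, records sort by (position, attrs, weight, mate
columns) — a total order. Appends merge with existing records and
rewrite the partition whole (point insertion into sorted columns is
O(N) regardless, and rewriting keeps all four files trivially
consistent). Two consequences used heavily in testing: writing any
permutation, or any batching, of the same hit multiset produces
byte-identical files; and importing the same input twice produces
byte-identical stores. Little-endian encoding is fixed and pinned by a
golden-byte test.

## Server and protocol

The protocol is line-oriented UTF-8 text with TSV payloads
(`docs/PROTOCOL.md`): trivially scriptable from any language, and easy
to fuzz — a property test feeds random bytes and asserts the server
answers with an error rather than dying. Stores are all-or-nothing per
request: every data line is parsed and validated before any file is
touched. Concurrency is single-writer/many-readers per alignment,
enforced with a per-alignment lock; a shared mtime-validated index
cache gives repeated queries on the same chromosome index-free-of-I/O
lookups and is invalidated on write. No authentication is provided;
the intended deployment is a curated read-mostly store inside a trusted
network, with write access controlled at that layer.

## Synthetic data generator

`hitdb.synthgen` draws a read population from a single seeded PCG64
stream and derives every view of the same draw: in-memory hit arrays, a
brute-force oracle, and SAM/BED fixture text. Defaults: 1,000 reads on
2 chromosomes, positions uniform on [10³, 10⁶], read length 36 (typical
of the short-read ChIP-Seq datasets this store targets), half the hits
on each strand, unit weights, single-end. Multi-mapping is modelled as
k ∈ {1, 2, 4} with probabilities 0.7/0.2/0.1 — a modest multi-mapping
tail — giving k hits of weight 1/k per read. Pairs are FR-oriented with
inserts uniform on [100, 300] bases; an optional interchromosomal
fraction exercises cross-chromosome routing. Arbitrary per-hit weights
("uniform" model) exist to exercise the weight column beyond 1/k values;
they are emitted through BED fixtures (score column), since SAM has no
per-record weight field.

The oracle answers count/sum/histogram/get queries by full scans of the
generator's arrays, sharing no code with the indexed query path; test
equivalence between the two is therefore evidence about the index and
scan logic, not a tautology. What the generator does *not* emulate:
base-level error models, fragment-length and GC biases, coverage
hotspots, or real chromosome size distributions. Passing tests
demonstrate storage/query correctness on data with the right shape, not
robustness to pathological real-world library artifacts.

## Problem sizes

The test suite and the acceptance script exercise stores up to 10⁷ hits
for the I/O-bound check (regions sized to return ~100 hits so the bound
is sharp at every n), 10⁴ pairs for the duplication/bijection check,
1,000 randomized query cases for oracle equivalence, and a 2,000-read
end-to-end round trip through SAM import, the server, and the client.
These sizes make every property measurable in seconds while spanning
two orders of magnitude in store size for the scaling claim.

## Known limitations

- No compression; the 10 B/record budget is already close to the
  entropy of sorted positions for typical densities, but runs of equal
  values in the attrs/weights columns are left uncompressed.
- Whole-partition rewrites make appends O(N); the design assumes
  import-once, query-many workloads.
- Deletion granularity is a partition (per chromosome or whole
  alignment), never individual hits.
- No span-overlap queries, transactions, TLS, or authentication.
- Record counts are derived from file sizes rather than a separate
  manifest; `hitdb verify` checks cross-file consistency explicitly.
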