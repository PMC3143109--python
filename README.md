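# hitdb

A compact column-store database and network server for genome-aligned
short-read positions.

## The problem

ChIP-Seq, DNase-Seq, methylation, and RNA-Seq analyses often need only
*where* each read mapped — not its sequence, base qualities, or mismatch
information. Full alignment formats (BAM) carry all of that and are
expensive to store and to query over a network; precomputed coverage
tracks (BigWig) are compact but freeze the bin width and discard
individual read positions. hitdb stores just the mapped positions — ten
bytes per hit — behind a small server, so peak callers, visualizers, and
cluster jobs can query thousands of datasets without a shared filesystem
or local copies.

## The model

An **alignment** is one read set mapped to one reference genome. A
**hit** is a mapped-read occurrence: chromosome *c* (an integer id), the
1-based coordinate *p* of the read's 5′ end (leftmost aligned base on
`+`, rightmost on `-`), the strand, the aligned span *ℓ* ∈ [1, 2¹⁵−1],
and a weight *w* — by convention *w* = 1/*k* for a read with *k*
alignments, so every read contributes total mass 1.

Per chromosome, hits live in three parallel column files sorted by *p*:
int32 positions (4 B), a uint16 word packing strand and length (2 B, one
strand bit + 15 length bits), and float32 weights (4 B). A fourth file is
a sparse block index with one 8-byte entry — (first position, record
offset) — per block of *B* = 1024 records, i.e. per 4 kb of the position
column. Binary search over the index followed by a bounded scan makes
any interval query **O(log n + m)** for *m* returned hits: at most
*m* + 2*B* records are decoded regardless of *n*. A 64 kb index file
addresses 8 × 2²⁰ records, so indexes for whole experiments stay cached
in server memory.

Read pairs are stored **twice** — once keyed by the left end, once by
the right (with the mate's chromosome, position, strand, and length as
extra columns) — so queries can anchor on either side of the pair.

The server answers per-read queries, counts, weight sums, and
server-side **histograms** at any caller-chosen bin width (hits binned
by 5′ position), all filterable by strand, weight threshold, and
single/paired endedness, over a line-oriented text protocol usable from
any language (`docs/PROTOCOL.md`; on-disk layout in `docs/FORMAT.md`).

## Worked example

Generate a synthetic read set (5,000 reads, 20% paired, multi-mapping
reads weighted 1/k), import it, and query it:

```sh
$ hitdb gen --out fixture.sam --seed 11 --n-reads 5000 --n-chroms 2 \
        --paired-fraction 0.2 --weight-model multiplicity
$ hitdb import fixture.sam --align store/ctcf_rep1
read=7970 hits=5970 pairs=1000 unmapped=0 too_long=0 supplementary=0 orphans=0 malformed=0
```

7,970 SAM records became 5,970 single-end hits (4,000 single-end reads,
some aligning 2 or 4 times) plus 1,000 pairs (each stored twice). Query
the store directly:

```sh
$ hitdb count --align store/ctcf_rep1
5970
$ hitdb weightsum --align store/ctcf_rep1
4000.0
$ hitdb count --align store/ctcf_rep1 --region chr1:200000-400000 --strand -
303
$ hitdb histogram --align store/ctcf_rep1 --region chr1:1-1000000 --binwidth 250000
1	710
250001	733
500001	721
750001	728
$ hitdb chroms --align store/ctcf_rep1
1	chr1	2892	503	503
2	chr2	3078	497	497
```

The weight sum is exactly 4,000 — one unit of mass per distinct read,
however many places it mapped. The histogram rows are bin start
positions (anchored at the region start) and hit counts; their total,
710 + 733 + 721 + 728 = 2,892, equals the chr1 single-end count in the
`chroms` listing, which also shows 503 pairs keyed by each end on chr1.

Or serve it and query over a socket:

```sh
hitdb serve --root store --port 52734 &
```

```python
from hitdb import Connection

with Connection("127.0.0.1", 52734) as c:
    c.count("ctcf_rep1", chrom=1, start=200_000, end=400_000, strand="-")  # 303
    c.histogram("ctcf_rep1", chrom=1, start=1, end=1_000_000, binwidth=250_000)
```

The same operations are available in-process via `hitdb.Alignment` and
the `hitdb.query` functions.

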