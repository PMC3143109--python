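# On-disk format

One directory per alignment. All multi-byte values are **little-endian**;
the layout is fixed so files are portable across implementations.

## Files

```
<align-dir>/
  chrommap.tsv                    chromosome name <TAB> integer id (optional sidecar)
  <chrom>.<part>.positions        int32   x N   sorted 5' positions
  <chrom>.<part>.attrs            uint16  x N   strand/length word
  <chrom>.<part>.weights          float32 x N   hit weights
  <chrom>.<part>.index            8-byte entries, one per 1024 records
  <chrom>.<part>.matechroms       int32   x N   (paired partitions only)
  <chrom>.<part>.matepositions    int32   x N   (paired partitions only)
  <chrom>.<part>.mateattrs        uint16  x N   (paired partitions only)
```

`<chrom>` is the non-negative integer chromosome id. `<part>` is one of:

- `single` — single-end hits;
- `pairedL` — read pairs keyed (and sorted) by the **left** end's 5′
  position; the anchor columns describe the left end, the mate columns
  the right end;
- `pairedR` — the same pairs keyed by the **right** end.

Record *i* of every column file of a partition describes the same hit;
all column files of a partition therefore hold exactly N records, and a
single-end record costs 4 + 2 + 4 = 10 bytes.

## Field encodings

- **positions**: 1-based 5′ coordinate, `1 ≤ pos ≤ 2³¹ − 1`. For a
  minus-strand hit this is the *rightmost* aligned base; the covered
  interval is `[pos − length + 1, pos]`.
- **attrs** (16-bit word): bit 15 is the strand (`0` = `+`, `1` = `-`);
  bits 0–14 are the aligned length, `1 ≤ length ≤ 32767`. An encoded
  length of 0 is invalid and treated as corruption.
- **weights**: IEEE-754 float32, finite, ≥ 0.
- **matechroms / matepositions / mateattrs**: the mate's chromosome id
  (int32; explicit so interchromosomal pairs are expressible), 5′
  position, and strand/length word, same encodings as above.

## Sort order

Records are stored in a canonical total order: ascending by
(position, attrs word, weight) — and for paired partitions further by
(mate chrom, mate position, mate attrs). Because the order is total,
writing any permutation of the same hit multiset produces byte-identical
files. Duplicate records are retained, never collapsed.

## Block index

One entry per block of **B = 1024** records (4096 bytes of the position
column), starting at record 0:

```
struct entry { int32 first_position; uint32 record_offset; }   // 8 bytes
```

Entry *k* has `record_offset = k·B` and `first_position =
positions[k·B]`; entry count is `ceil(N / B)`. Entries are strictly
increasing in offset and non-decreasing in first position. A 64 kb index
(8192 entries) therefore addresses 8192 × 1024 = 8,388,608 records; at
16 kb block granularity the same index bytes would address four times
as many.

## chrommap.tsv

Two tab-separated columns, `name<TAB>id`, one line per chromosome, ids
unique. Written by the importer; query tools use it to resolve
chromosome names. Stores remain readable without it (ids are the file
names).

## Writer contract

Appends merge new records with existing ones and atomically rewrite the
whole partition (write-temp-then-rename per file) including the index.
Deletion removes whole partitions and is idempotent. Single writer per
alignment; readers may run concurrently with each other.
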