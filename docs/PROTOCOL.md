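# Wire protocol

Line-oriented UTF-8 text over TCP; newline-terminated requests, TSV
payloads. Queries can be issued from any language with a socket. Default
port: 52734.

## Requests

One request per line:

```
VERB key=value key=value ...
```

Keys are case-insensitive; values contain no whitespace. `STORE` and
`STOREPAIRED` are followed by exactly `count` data lines (tab-separated,
see below). The connection stays open across requests.

## Responses

The first line is the status:

```
OK <n>                     n payload lines follow
ERROR <code> <message>     no payload; the connection stays open
```

Error codes: `400` malformed request or bad field, `404` alignment not
found, `500` internal error.

## Common parameters

| param       | meaning                                                      |
|-------------|--------------------------------------------------------------|
| `align`     | alignment name (directory under the server root); required by every verb except SHUTDOWN/BYE |
| `chrom`     | integer chromosome id                                        |
| `start`,`end` | 1-based inclusive interval bounds over 5′ positions        |
| `strand`    | `+`, `-`, or `both` (default `both`)                         |
| `minweight` | keep hits with weight ≥ threshold (inclusive)                |
| `endedness` | `single` (default), `pairedL`, `pairedR` — which partition to query; paired queries match on the keyed side's position/strand |
| `projection`| `full` (default), `positions`, `weights` (GETHITS only)      |
| `binwidth`  | positive integer, bases (HISTOGRAM only)                     |
| `mode`      | `count` (default) or `weight` (HISTOGRAM only)               |

## Verbs

### STORE `align= chrom= count=`
Followed by `count` lines `pos<TAB>strand<TAB>length<TAB>weight`.
All-or-nothing: a parse failure on any line (reported with its line
number) persists nothing. Response `OK 0`.

### STOREPAIRED `align= count=`
Followed by `count` lines
`chrom<TAB>pos<TAB>strand<TAB>length<TAB>weight<TAB>matechrom<TAB>matepos<TAB>matestrand<TAB>matelength`,
each pair anchored on its left end (smaller (chrom, 5′ pos) key). Each
pair is stored twice (left- and right-keyed). Response `OK 0`.

### DELETE `align= [chrom=] [endedness=single|paired|both]`
Removes the named partition(s); idempotent. Response `OK 0`.

### CHROMS `align=`
Payload lines: `chrom<TAB>n_single<TAB>n_pairedL<TAB>n_pairedR`, one per
chromosome with ≥ 1 stored record.

### COUNT `align= [chrom= [start= end=]] [filters]`
Payload: one line with the integer count. Without `chrom`: the whole
alignment; with `chrom` only: the whole chromosome.

### WEIGHTSUM — same parameters as COUNT
Payload: one line with the double-precision weight sum.

### GETHITS `align= chrom= start= end= [projection=] [filters]`
Payload, one line per hit in position order:

- `full`, single: `pos<TAB>strand<TAB>length<TAB>weight`
- `full`, paired: `pos<TAB>strand<TAB>length<TAB>weight<TAB>matechrom<TAB>matepos<TAB>matestrand<TAB>matelength`
- `positions`: `pos`
- `weights`: `weight`

### HISTOGRAM `align= chrom= start= end= binwidth= [mode=] [filters]`
Payload lines `binstart<TAB>value`, ascending, empty bins omitted. Bins
anchor at `start`: a hit at p falls in the bin starting at
`start + binwidth*floor((p-start)/binwidth)`.

### SHUTDOWN
Response `OK 0`, then the server stops accepting connections.

### BYE
Response `OK 0`, then the server closes this connection.

## Notes

- Weights are serialised as the shortest decimal that round-trips
  through float32; clients comparing weights should compare at float32
  precision.
- A region query on a chromosome with no stored reads returns `OK 0`,
  not an error.
- Concurrency: many readers, single writer per alignment (writes are
  serialised server-side with a per-alignment lock).
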