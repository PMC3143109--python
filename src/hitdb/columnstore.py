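"""On-disk column store: one directory per alignment, parallel column
files per chromosome, and a sparse block index over the sorted positions.

Layout (all integers little-endian; full byte-level description in
docs/FORMAT.md):

    <align-dir>/
      chrommap.tsv                       # optional name <-> id sidecar
      <chrom>.<part>.positions           # int32 x N, non-decreasing
      <chrom>.<part>.attrs               # uint16 x N (strand bit + 15-bit length)
      <chrom>.<part>.weights             # float32 x N
      <chrom>.<part>.index               # (int32 first-pos, uint32 offset) x ceil(N/B)
      <chrom>.<part>.matechroms          # int32 x N      (paired partitions only)
      <chrom>.<part>.matepositions       # int32 x N      (paired partitions only)
      <chrom>.<part>.mateattrs           # uint16 x N     (paired partitions only)

``part`` is ``single``, ``pairedL`` (records keyed/sorted by the pair's
left end) or ``pairedR`` (keyed by the right end).  Record ``i`` of every
column file of a partition describes the same hit; positions are sorted,
and the index holds one 8-byte entry per block of B = 1024 records —
4 kb of the 4-byte position column, so a 64 kb index file addresses
8 M+ records and stays cheap to cache.

Appends merge with existing records and rewrite the partition whole:
with sorted columns a point insertion is O(N) anyway, and rewriting keeps
the format trivially consistent.  Records are kept in a canonical total
order, so writing any permutation of the same hit multiset produces
byte-identical files.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np

from .hitcore import (
    ATTR_DTYPE,
    CHROM_DTYPE,
    INDEX_DTYPE,
    PAIRED_LEFT,
    PAIRED_RIGHT,
    POS_DTYPE,
    SINGLE,
    WEIGHT_DTYPE,
    CorruptRecordError,
    HitArray,
    PairedHit,
    PairedHitArray,
    SingleHit,
)

__all__ = [
    "BLOCK_RECORDS",
    "PARTS",
    "Alignment",
    "IndexCache",
    "build_index",
    "StoreNotFoundError",
]

#: Records per index block: 1024 records = 4 kb of the position column,
#: the dense end of the useful 4-16 kb granularity range (a denser index
#: buys nothing once a block fits in one disk read).
BLOCK_RECORDS = 1024

PARTS = (SINGLE, PAIRED_LEFT, PAIRED_RIGHT)

_SINGLE_COLUMNS = (("positions", POS_DTYPE), ("attrs", ATTR_DTYPE), ("weights", WEIGHT_DTYPE))
_PAIRED_COLUMNS = _SINGLE_COLUMNS + (
    ("matechroms", CHROM_DTYPE),
    ("matepositions", POS_DTYPE),
    ("mateattrs", ATTR_DTYPE),
)

_CHROM_FILE_RE = re.compile(r"^(\d+)\.(single|pairedL|pairedR)\.positions$")

CHROMMAP_FILE = "chrommap.tsv"


class StoreNotFoundError(FileNotFoundError):
    """The requested alignment directory does not exist."""


def build_index(positions: np.ndarray) -> np.ndarray:
    """Build the sparse block index for a sorted position column.

    One entry per :data:`BLOCK_RECORDS` records starting at record 0;
    each entry records the block's first position and its record offset.
    """
    positions = np.asarray(positions, dtype=POS_DTYPE)
    if positions.size and np.any(np.diff(positions) < 0):
        raise CorruptRecordError("positions not sorted; cannot index")
    offsets = np.arange(0, len(positions), BLOCK_RECORDS, dtype=np.uint32)
    idx = np.empty(len(offsets), dtype=INDEX_DTYPE)
    idx["offset"] = offsets
    idx["first"] = positions[offsets.astype(np.int64)] if len(offsets) else []
    return idx


class IndexCache:
    """mtime-validated cache of loaded index arrays, shared by a server
    across connections so repeated queries avoid re-reading index files."""

    def __init__(self) -> None:
        self._entries: Dict[Path, tuple[float, np.ndarray]] = {}

    def get(self, path: Path) -> Optional[np.ndarray]:
        try:
            mtime = path.stat().st_mtime_ns
        except FileNotFoundError:
            self._entries.pop(path, None)
            return None
        hit = self._entries.get(path)
        if hit is not None and hit[0] == mtime:
            return hit[1]
        idx = np.fromfile(path, dtype=INDEX_DTYPE)
        self._entries[path] = (mtime, idx)
        return idx

    def invalidate(self, path: Path) -> None:
        self._entries.pop(path, None)

    def __len__(self) -> int:
        return len(self._entries)


def _atomic_write(path: Path, data: np.ndarray) -> None:
    tmp = path.with_name(path.name + ".tmp")
    data.tofile(tmp)
    os.replace(tmp, path)


class Alignment:
    """One alignment: a directory of per-chromosome column partitions.

    Parameters
    ----------
    path
        The alignment directory.
    create
        Create the directory if missing; otherwise a missing directory
        raises :class:`StoreNotFoundError`.
    index_cache
        Optional shared :class:`IndexCache` (used by the server).
    """

    def __init__(self, path: Union[str, Path], create: bool = False,
                 index_cache: Optional[IndexCache] = None) -> None:
        self.path = Path(path)
        if not self.path.is_dir():
            if create:
                self.path.mkdir(parents=True, exist_ok=True)
            else:
                raise StoreNotFoundError(str(self.path))
        self._cache = index_cache

    # -- file naming ---------------------------------------------------

    def _file(self, chrom: int, part: str, column: str) -> Path:
        return self.path / f"{chrom}.{part}.{column}"

    def _columns(self, part: str):
        return _SINGLE_COLUMNS if part == SINGLE else _PAIRED_COLUMNS

    # -- metadata ------------------------------------------------------

    def count(self, chrom: int, part: str = SINGLE) -> int:
        """Record count of one partition, derived from the position file size."""
        f = self._file(chrom, part, "positions")
        try:
            size = f.stat().st_size
        except FileNotFoundError:
            return 0
        if size % POS_DTYPE.itemsize:
            raise CorruptRecordError(f"{f}: size {size} not a multiple of 4")
        return size // POS_DTYPE.itemsize

    def chroms(self) -> Dict[int, Dict[str, int]]:
        """Chromosomes with at least one stored record, with per-partition counts."""
        out: Dict[int, Dict[str, int]] = {}
        for f in self.path.iterdir():
            m = _CHROM_FILE_RE.match(f.name)
            if not m:
                continue
            chrom, part = int(m.group(1)), m.group(2)
            n = self.count(chrom, part)
            if n:
                out.setdefault(chrom, {p: 0 for p in PARTS})[part] = n
        return {c: v for c, v in sorted(out.items())}

    # -- chromosome name mapping ----------------------------------------

    def load_chrommap(self) -> Dict[str, int]:
        path = self.path / CHROMMAP_FILE
        mapping: Dict[str, int] = {}
        if path.exists():
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                name, cid = line.split("\t")
                mapping[name] = int(cid)
        return mapping

    def save_chrommap(self, mapping: Dict[str, int]) -> None:
        ids = list(mapping.values())
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome map is not bijective")
        lines = [f"{name}\t{cid}" for name, cid in sorted(mapping.items(), key=lambda kv: kv[1])]
        (self.path / CHROMMAP_FILE).write_text("\n".join(lines) + ("\n" if lines else ""))

    # -- reading -------------------------------------------------------

    def _read_column(self, chrom: int, part: str, column: str, dtype,
                     lo: int, hi: int) -> np.ndarray:
        f = self._file(chrom, part, column)
        if not f.exists():
            return np.empty(0, dtype=dtype)
        with open(f, "rb") as fh:
            fh.seek(lo * dtype.itemsize)
            data = np.fromfile(fh, dtype=dtype, count=hi - lo)
        if len(data) != hi - lo:
            raise CorruptRecordError(f"{f}: wanted records [{lo},{hi}), file too short")
        return data

    def read_index(self, chrom: int, part: str = SINGLE) -> np.ndarray:
        f = self._file(chrom, part, "index")
        if self._cache is not None:
            idx = self._cache.get(f)
            return idx if idx is not None else np.empty(0, dtype=INDEX_DTYPE)
        if not f.exists():
            return np.empty(0, dtype=INDEX_DTYPE)
        return np.fromfile(f, dtype=INDEX_DTYPE)

    def read_positions(self, chrom: int, part: str, lo: int = 0,
                       hi: Optional[int] = None) -> np.ndarray:
        n = self.count(chrom, part)
        hi = n if hi is None else hi
        self._check_range(lo, hi, n)
        return self._read_column(chrom, part, "positions", POS_DTYPE, lo, hi)

    def read_attrs(self, chrom: int, part: str, lo: int = 0,
                   hi: Optional[int] = None) -> np.ndarray:
        n = self.count(chrom, part)
        hi = n if hi is None else hi
        self._check_range(lo, hi, n)
        return self._read_column(chrom, part, "attrs", ATTR_DTYPE, lo, hi)

    def read_weights(self, chrom: int, part: str, lo: int = 0,
                     hi: Optional[int] = None) -> np.ndarray:
        n = self.count(chrom, part)
        hi = n if hi is None else hi
        self._check_range(lo, hi, n)
        return self._read_column(chrom, part, "weights", WEIGHT_DTYPE, lo, hi)

    @staticmethod
    def _check_range(lo: int, hi: int, n: int) -> None:
        if not 0 <= lo <= hi <= n:
            raise IndexError(f"record range [{lo},{hi}) outside 0..{n}")

    def read_single(self, chrom: int, lo: int = 0, hi: Optional[int] = None) -> HitArray:
        """Decode a record range of the single-end partition."""
        n = self.count(chrom, SINGLE)
        hi = n if hi is None else hi
        self._check_range(lo, hi, n)
        return HitArray(
            self._read_column(chrom, SINGLE, "positions", POS_DTYPE, lo, hi),
            self._read_column(chrom, SINGLE, "attrs", ATTR_DTYPE, lo, hi),
            self._read_column(chrom, SINGLE, "weights", WEIGHT_DTYPE, lo, hi),
        )

    def read_paired(self, chrom: int, part: str = PAIRED_LEFT,
                    lo: int = 0, hi: Optional[int] = None) -> PairedHitArray:
        """Decode a record range of a paired partition (anchor = keyed side)."""
        if part not in (PAIRED_LEFT, PAIRED_RIGHT):
            raise ValueError(f"paired partition must be pairedL/pairedR, got {part!r}")
        n = self.count(chrom, part)
        hi = n if hi is None else hi
        self._check_range(lo, hi, n)
        return PairedHitArray(
            np.full(hi - lo, chrom, dtype=CHROM_DTYPE),
            self._read_column(chrom, part, "positions", POS_DTYPE, lo, hi),
            self._read_column(chrom, part, "attrs", ATTR_DTYPE, lo, hi),
            self._read_column(chrom, part, "weights", WEIGHT_DTYPE, lo, hi),
            self._read_column(chrom, part, "matechroms", CHROM_DTYPE, lo, hi),
            self._read_column(chrom, part, "matepositions", POS_DTYPE, lo, hi),
            self._read_column(chrom, part, "mateattrs", ATTR_DTYPE, lo, hi),
        )

    # -- writing -------------------------------------------------------

    def append_single(self, chrom: int, hits: Union[HitArray, Iterable[SingleHit]]) -> int:
        """Merge hits into the chromosome's single-end partition.

        Existing and incoming records are combined, re-sorted into the
        canonical order, and all three column files plus the index are
        rewritten consistently.  Returns the new record count.
        """
        if chrom < 0:
            raise ValueError(f"chrom id must be non-negative, got {chrom}")
        if not isinstance(hits, HitArray):
            hits = HitArray.from_hits(hits)
        hits.validate()
        merged = self.read_single(chrom).concat(hits).sorted()
        self._write_partition(chrom, SINGLE, {
            "positions": merged.pos,
            "attrs": merged.attrs,
            "weights": merged.weight,
        })
        return len(merged)

    def append_paired(self, pairs: Union[PairedHitArray, Iterable[PairedHit]]) -> int:
        """Store pairs, each twice: left-keyed and right-keyed.

        Input pairs must be anchored on their *left* end (the end with the
        smaller (chrom, 5'-pos) key).  Each pair yields one record in the
        left-keyed partition of its left chromosome (sorted by left
        position) and one in the right-keyed partition of its right
        chromosome (sorted by right position).  Returns the number of
        stored records (2x the pair count).
        """
        if not isinstance(pairs, PairedHitArray):
            pairs = PairedHitArray.from_pairs(pairs)
        for keyed, part in ((pairs, PAIRED_LEFT), (pairs.flipped(), PAIRED_RIGHT)):
            for chrom in np.unique(keyed.chrom):
                sub = keyed.take(keyed.chrom == chrom)
                merged = self.read_paired(int(chrom), part).concat(sub).sorted()
                self._write_partition(int(chrom), part, {
                    "positions": merged.pos,
                    "attrs": merged.attrs,
                    "weights": merged.weight,
                    "matechroms": merged.matechrom,
                    "matepositions": merged.matepos,
                    "mateattrs": merged.mateattrs,
                })
        return 2 * len(pairs)

    def _write_partition(self, chrom: int, part: str, columns: Dict[str, np.ndarray]) -> None:
        for (name, dtype) in self._columns(part):
            _atomic_write(self._file(chrom, part, name), columns[name].astype(dtype))
        idxfile = self._file(chrom, part, "index")
        _atomic_write(idxfile, build_index(columns["positions"]))
        if self._cache is not None:
            self._cache.invalidate(idxfile)

    # -- deleting ------------------------------------------------------

    def delete(self, chrom: Optional[int] = None, endedness: str = "both") -> None:
        """Remove a partition's files (idempotent).

        endedness: ``single``, ``paired`` (both keyings) or ``both``.
        ``chrom=None`` deletes across all chromosomes.
        """
        parts: tuple[str, ...]
        if endedness == SINGLE:
            parts = (SINGLE,)
        elif endedness == "paired":
            parts = (PAIRED_LEFT, PAIRED_RIGHT)
        elif endedness == "both":
            parts = PARTS
        else:
            raise ValueError(f"endedness must be single/paired/both, got {endedness!r}")
        chroms = [chrom] if chrom is not None else list(self.chroms())
        for c in chroms:
            for part in parts:
                for (name, _dtype) in self._columns(part):
                    self._file(c, part, name).unlink(missing_ok=True)
                idxfile = self._file(c, part, "index")
                idxfile.unlink(missing_ok=True)
                if self._cache is not None:
                    self._cache.invalidate(idxfile)

    # -- integrity -----------------------------------------------------

    def verify(self) -> List[str]:
        """Scan every partition for format violations.

        Returns a list of human-readable problems (empty = store is
        consistent): column files whose sizes disagree, unsorted
        positions, and indexes that do not match the data.
        """
        problems: List[str] = []
        seen: Dict[tuple[int, str], None] = {}
        for f in sorted(self.path.iterdir()):
            m = re.match(r"^(\d+)\.(single|pairedL|pairedR)\.", f.name)
            if m:
                seen.setdefault((int(m.group(1)), m.group(2)))
        for chrom, part in seen:
            try:
                n = self.count(chrom, part)
            except CorruptRecordError as e:
                problems.append(str(e))
                continue
            for (name, dtype) in self._columns(part):
                f = self._file(chrom, part, name)
                expected = n * dtype.itemsize
                actual = f.stat().st_size if f.exists() else -1
                if actual != expected:
                    problems.append(
                        f"{f.name}: expected {expected} bytes for {n} records, found {actual}"
                    )
            if problems:
                continue
            pos = self.read_positions(chrom, part)
            if pos.size and np.any(np.diff(pos) < 0):
                problems.append(f"{chrom}.{part}: positions not sorted")
                continue
            idxfile = self._file(chrom, part, "index")
            idx = np.fromfile(idxfile, dtype=INDEX_DTYPE) if idxfile.exists() else None
            if idx is None:
                problems.append(f"{chrom}.{part}: missing index file")
            elif not np.array_equal(idx, build_index(pos)):
                problems.append(f"{chrom}.{part}: index does not match data")
            try:
                attrs = self.read_attrs(chrom, part)
                if attrs.size and int((attrs & 0x7FFF).min()) == 0:
                    problems.append(f"{chrom}.{part}: record with encoded length 0")
            except CorruptRecordError as e:
                problems.append(str(e))
        return problems
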