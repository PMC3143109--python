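"""Core domain types for genome-aligned hit storage.

A *hit* is a genomic position to which a sequencing read is mapped: the
chromosome (a small non-negative integer), the 1-based coordinate of the
read's 5' end, the strand, the aligned span in bases, and a weight
(typically 1/k for a read with k alignments, so a multi-mapping read
contributes total mass 1).

Hits are the atomic record of the column store.  On disk a hit occupies
ten bytes: a 32-bit position, a 16-bit word packing strand and length
(one strand bit, 15 length bits), and a 32-bit float weight.  This module
owns those semantics — the bit packing, field ranges, and the in-memory
containers — independent of any file format.

Coordinates are 1-based and inclusive throughout, matching SAM.  For a
minus-strand hit ``pos`` is the 5' end, i.e. the *highest* aligned
coordinate; the covered interval is ``[pos - length + 1, pos]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

import math

import numpy as np

__all__ = [
    "MAX_POS",
    "MAX_LENGTH",
    "STRAND_BIT",
    "POS_DTYPE",
    "ATTR_DTYPE",
    "WEIGHT_DTYPE",
    "CHROM_DTYPE",
    "INDEX_DTYPE",
    "HitRangeError",
    "CorruptRecordError",
    "pack_strand_length",
    "unpack_strand_length",
    "pack_attrs",
    "unpack_attrs",
    "SingleHit",
    "PairedHit",
    "Region",
    "HitFilter",
    "Histogram",
    "AlignmentMeta",
    "HitArray",
    "PairedHitArray",
    "SINGLE",
    "PAIRED_LEFT",
    "PAIRED_RIGHT",
]

MAX_POS = 2**31 - 1
MAX_LENGTH = 2**15 - 1  # 15-bit length field
STRAND_BIT = 1 << 15  # bit 15: 0 = forward (+), 1 = reverse (-)

# All on-disk integers are little-endian; see docs/FORMAT.md.
POS_DTYPE = np.dtype("<i4")
ATTR_DTYPE = np.dtype("<u2")
WEIGHT_DTYPE = np.dtype("<f4")
CHROM_DTYPE = np.dtype("<i4")
INDEX_DTYPE = np.dtype([("first", "<i4"), ("offset", "<u4")])

# Partition names: every chromosome of an alignment has up to three
# independent record partitions.
SINGLE = "single"
PAIRED_LEFT = "pairedL"
PAIRED_RIGHT = "pairedR"


class HitRangeError(ValueError):
    """A hit field is outside its storable range."""


class CorruptRecordError(ValueError):
    """A decoded record violates the format (e.g. encoded length 0)."""


def pack_strand_length(strand: str, length: int) -> int:
    """Pack strand and aligned length into a 16-bit word.

    Bit 15 carries the strand (0 = ``+``, 1 = ``-``); bits 0-14 carry the
    length, which must be in ``1..32767``.
    """
    if strand not in ("+", "-"):
        raise HitRangeError(f"strand must be '+' or '-', got {strand!r}")
    if not 1 <= length <= MAX_LENGTH:
        raise HitRangeError(f"length {length} outside 1..{MAX_LENGTH}")
    return (STRAND_BIT if strand == "-" else 0) | length


def unpack_strand_length(word: int) -> tuple[str, int]:
    """Inverse of :func:`pack_strand_length`.

    Raises :class:`CorruptRecordError` for an encoded length of zero,
    which no valid writer produces.
    """
    if not 0 <= word <= 0xFFFF:
        raise HitRangeError(f"attrs word {word} is not a 16-bit value")
    length = word & MAX_LENGTH
    if length == 0:
        raise CorruptRecordError("encoded hit length 0 (corrupt record)")
    return ("-" if word & STRAND_BIT else "+", length)


def pack_attrs(minus: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Vectorised packing: boolean minus-strand flags + lengths -> uint16."""
    lengths = np.asarray(lengths)
    if lengths.size and (lengths.min() < 1 or lengths.max() > MAX_LENGTH):
        raise HitRangeError("length outside 1..32767")
    out = lengths.astype(np.uint16)
    out = out | (np.asarray(minus, dtype=bool).astype(np.uint16) << 15)
    return out.astype(ATTR_DTYPE)


def unpack_attrs(attrs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised unpacking: uint16 words -> (minus flags, lengths)."""
    attrs = np.asarray(attrs, dtype=np.uint16)
    lengths = (attrs & MAX_LENGTH).astype(np.int32)
    if attrs.size and lengths.min() == 0:
        raise CorruptRecordError("encoded hit length 0 (corrupt record)")
    minus = (attrs & STRAND_BIT) != 0
    return minus, lengths


def _check_chrom(chrom: int, name: str = "chrom") -> None:
    if chrom < 0:
        raise HitRangeError(f"{name} id must be non-negative, got {chrom}")


def _check_pos(pos: int, name: str = "pos") -> None:
    if not 1 <= pos <= MAX_POS:
        raise HitRangeError(f"{name} {pos} outside 1..{MAX_POS}")


def _check_weight(weight: float) -> None:
    if not (weight >= 0 and math.isfinite(weight)):
        raise HitRangeError(f"weight must be finite and >= 0, got {weight}")


@dataclass(frozen=True, slots=True)
class SingleHit:
    """One mapped-read occurrence.

    ``pos`` is the 5' coordinate: the leftmost aligned base on ``+``, the
    rightmost on ``-``.
    """

    chrom: int
    pos: int
    strand: str
    length: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        _check_chrom(self.chrom)
        _check_pos(self.pos)
        pack_strand_length(self.strand, self.length)  # validates strand+length
        _check_weight(self.weight)

    @property
    def span(self) -> tuple[int, int]:
        """Covered interval (start, end), 1-based inclusive."""
        if self.strand == "+":
            return self.pos, self.pos + self.length - 1
        return self.pos - self.length + 1, self.pos


@dataclass(frozen=True, slots=True)
class PairedHit:
    """A read pair: an anchor-side hit plus its mate's coordinates.

    The weight applies to the pair as a whole.  In the store each pair
    appears twice — once anchored on the left end (sorted by its
    position) and once anchored on the right end — so queries can select
    pairs by either side.
    """

    chrom: int
    pos: int
    strand: str
    length: int
    weight: float
    matechrom: int
    matepos: int
    matestrand: str
    matelength: int

    def __post_init__(self) -> None:
        _check_chrom(self.chrom)
        _check_pos(self.pos)
        pack_strand_length(self.strand, self.length)
        _check_weight(self.weight)
        _check_chrom(self.matechrom, "matechrom")
        _check_pos(self.matepos, "matepos")
        pack_strand_length(self.matestrand, self.matelength)

    def flipped(self) -> "PairedHit":
        """The same pair anchored on the other end."""
        return PairedHit(
            chrom=self.matechrom,
            pos=self.matepos,
            strand=self.matestrand,
            length=self.matelength,
            weight=self.weight,
            matechrom=self.chrom,
            matepos=self.pos,
            matestrand=self.strand,
            matelength=self.length,
        )


@dataclass(frozen=True, slots=True)
class Region:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        _check_chrom(self.chrom)
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


@dataclass(frozen=True, slots=True)
class HitFilter:
    """Selection predicate applied by every query.

    strand
        ``"+"``, ``"-"`` or ``"both"``.
    minweight
        Keep hits with ``weight >= minweight`` (inclusive); ``None``
        disables weight filtering.
    endedness
        Which partition to query: ``"single"``, ``"pairedL"``
        (pairs keyed by their left end) or ``"pairedR"``.
    """

    strand: str = "both"
    minweight: Optional[float] = None
    endedness: str = SINGLE

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"strand filter must be +, - or both: {self.strand!r}")
        if self.minweight is not None and not (
            self.minweight >= 0 and math.isfinite(self.minweight)
        ):
            raise ValueError(f"minweight must be finite and >= 0: {self.minweight}")
        if self.endedness not in (SINGLE, PAIRED_LEFT, PAIRED_RIGHT):
            raise ValueError(f"unknown endedness {self.endedness!r}")


@dataclass(frozen=True, slots=True)
class Histogram:
    """Binned counts or weight sums over a region.

    Bins anchor at ``region.start``: a hit at position ``p`` falls in the
    bin starting at ``region.start + binwidth * floor((p - start) / binwidth)``.
    Empty bins are omitted; every stored value is > 0.
    """

    region: Region
    binwidth: int
    mode: str  # "count" | "weight"
    bins: Dict[int, float]

    @property
    def total(self) -> float:
        return sum(self.bins.values())


@dataclass
class AlignmentMeta:
    """Summary of one alignment: chromosome ids, per-partition record
    counts, and the chromosome name <-> integer id mapping."""

    name: str
    counts: Dict[int, Dict[str, int]] = field(default_factory=dict)
    chrom_names: Dict[str, int] = field(default_factory=dict)


def _as_array(values, dtype) -> np.ndarray:
    a = np.asarray(values, dtype=dtype)
    if a.ndim != 1:
        raise ValueError("column must be one-dimensional")
    return a


class HitArray:
    """Struct-of-arrays container for single-end hits of one chromosome.

    Columns mirror the on-disk layout: ``pos`` (int32), ``attrs``
    (uint16 strand/length word), ``weight`` (float32).
    """

    __slots__ = ("pos", "attrs", "weight")

    def __init__(self, pos, attrs, weight) -> None:
        self.pos = _as_array(pos, POS_DTYPE)
        self.attrs = _as_array(attrs, ATTR_DTYPE)
        self.weight = _as_array(weight, WEIGHT_DTYPE)
        if not (len(self.pos) == len(self.attrs) == len(self.weight)):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def empty(cls) -> "HitArray":
        return cls([], [], [])

    @classmethod
    def from_hits(cls, hits: Iterable[SingleHit]) -> "HitArray":
        hits = list(hits)
        return cls(
            [h.pos for h in hits],
            [pack_strand_length(h.strand, h.length) for h in hits],
            [h.weight for h in hits],
        )

    @classmethod
    def from_fields(cls, pos, minus, lengths, weight) -> "HitArray":
        return cls(pos, pack_attrs(minus, lengths), weight)

    def to_hits(self, chrom: int) -> List[SingleHit]:
        minus, lengths = unpack_attrs(self.attrs)
        return [
            SingleHit(
                chrom=chrom,
                pos=int(p),
                strand="-" if m else "+",
                length=int(ln),
                weight=float(w),
            )
            for p, m, ln, w in zip(self.pos, minus, lengths, self.weight)
        ]

    @property
    def minus(self) -> np.ndarray:
        return (self.attrs & STRAND_BIT) != 0

    @property
    def length(self) -> np.ndarray:
        return (self.attrs & MAX_LENGTH).astype(np.int32)

    def validate(self) -> None:
        if len(self):
            if self.pos.min() < 1:
                raise HitRangeError("position < 1")
            if int((self.attrs & MAX_LENGTH).min()) == 0:
                raise HitRangeError("length 0")
            w = self.weight
            if not np.all(np.isfinite(w)) or (len(w) and w.min() < 0):
                raise HitRangeError("weight must be finite and >= 0")

    def take(self, idx) -> "HitArray":
        return HitArray(self.pos[idx], self.attrs[idx], self.weight[idx])

    def sorted(self) -> "HitArray":
        """Canonical total order: (pos, attrs, weight) lexicographic, so any
        permutation of the same multiset serialises byte-identically."""
        order = np.lexsort((self.weight, self.attrs, self.pos))
        return self.take(order)

    def concat(self, other: "HitArray") -> "HitArray":
        return HitArray(
            np.concatenate([self.pos, other.pos]),
            np.concatenate([self.attrs, other.attrs]),
            np.concatenate([self.weight, other.weight]),
        )

    def __iter__(self) -> Iterator[tuple[int, int, float]]:
        return zip(self.pos.tolist(), self.attrs.tolist(), self.weight.tolist())


class PairedHitArray:
    """Struct-of-arrays container for paired records.

    ``chrom`` is the anchor side's chromosome (used for routing; it is
    implicit, not stored, inside a chromosome's files).  Mate columns add
    the mate's chromosome, position, and strand/length word.
    """

    __slots__ = ("chrom", "pos", "attrs", "weight", "matechrom", "matepos", "mateattrs")

    def __init__(self, chrom, pos, attrs, weight, matechrom, matepos, mateattrs) -> None:
        self.chrom = _as_array(chrom, CHROM_DTYPE)
        self.pos = _as_array(pos, POS_DTYPE)
        self.attrs = _as_array(attrs, ATTR_DTYPE)
        self.weight = _as_array(weight, WEIGHT_DTYPE)
        self.matechrom = _as_array(matechrom, CHROM_DTYPE)
        self.matepos = _as_array(matepos, POS_DTYPE)
        self.mateattrs = _as_array(mateattrs, ATTR_DTYPE)
        n = len(self.pos)
        for col in (self.chrom, self.attrs, self.weight, self.matechrom, self.matepos, self.mateattrs):
            if len(col) != n:
                raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def empty(cls) -> "PairedHitArray":
        return cls([], [], [], [], [], [], [])

    @classmethod
    def from_pairs(cls, pairs: Iterable[PairedHit]) -> "PairedHitArray":
        pairs = list(pairs)
        return cls(
            [p.chrom for p in pairs],
            [p.pos for p in pairs],
            [pack_strand_length(p.strand, p.length) for p in pairs],
            [p.weight for p in pairs],
            [p.matechrom for p in pairs],
            [p.matepos for p in pairs],
            [pack_strand_length(p.matestrand, p.matelength) for p in pairs],
        )

    def to_pairs(self) -> List[PairedHit]:
        out = []
        for i in range(len(self)):
            s, ln = unpack_strand_length(int(self.attrs[i]))
            ms, mln = unpack_strand_length(int(self.mateattrs[i]))
            out.append(
                PairedHit(
                    chrom=int(self.chrom[i]),
                    pos=int(self.pos[i]),
                    strand=s,
                    length=ln,
                    weight=float(self.weight[i]),
                    matechrom=int(self.matechrom[i]),
                    matepos=int(self.matepos[i]),
                    matestrand=ms,
                    matelength=mln,
                )
            )
        return out

    @property
    def minus(self) -> np.ndarray:
        return (self.attrs & STRAND_BIT) != 0

    def flipped(self) -> "PairedHitArray":
        """Anchor every pair on its other end (swap anchor and mate)."""
        return PairedHitArray(
            self.matechrom, self.matepos, self.mateattrs, self.weight,
            self.chrom, self.pos, self.attrs,
        )

    def take(self, idx) -> "PairedHitArray":
        return PairedHitArray(
            self.chrom[idx], self.pos[idx], self.attrs[idx], self.weight[idx],
            self.matechrom[idx], self.matepos[idx], self.mateattrs[idx],
        )

    def sorted(self) -> "PairedHitArray":
        order = np.lexsort(
            (self.mateattrs, self.matepos, self.matechrom,
             self.weight, self.attrs, self.pos)
        )
        return self.take(order)

    def concat(self, other: "PairedHitArray") -> "PairedHitArray":
        return PairedHitArray(
            np.concatenate([self.chrom, other.chrom]),
            np.concatenate([self.pos, other.pos]),
            np.concatenate([self.attrs, other.attrs]),
            np.concatenate([self.weight, other.weight]),
            np.concatenate([self.matechrom, other.matechrom]),
            np.concatenate([self.matepos, other.matepos]),
            np.concatenate([self.mateattrs, other.mateattrs]),
        )
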