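"""Indexed interval queries, aggregates, and histograms over an alignment.

Every query selects hits by their stored 5' position (the sort and index
key), not by span overlap: a minus-strand hit whose covered bases reach
into a region but whose 5' end lies outside it is not returned.  For
paired queries the filter's endedness picks the left- or right-keyed
partition and matching is on the keyed side's position and strand.

The sparse block index gives O(log n) location of the first candidate
block; the scan then decodes at most m + 2B records for a query returning
m hits (B = block size), independent of the store size n — the testable
form of the O(log n + m) query-cost contract.  :class:`QueryStats`
instruments exactly that record-decode count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from .columnstore import Alignment
from .hitcore import (
    SINGLE,
    STRAND_BIT,
    Histogram,
    HitArray,
    HitFilter,
    PairedHitArray,
    Region,
)

__all__ = [
    "QueryStats",
    "locate",
    "get_hits",
    "count_hits",
    "sum_weights",
    "histogram",
    "list_chromosomes",
]


@dataclass
class QueryStats:
    """Instrumentation: how many records a query decoded."""

    records_decoded: int = 0


def locate(index: np.ndarray, position: int) -> int:
    """Record offset of the block whose first position is the greatest
    one <= ``position`` (0 if the position precedes every entry).

    No record with ``pos >= position`` lies before the returned offset,
    so a scan starting there cannot miss hits.
    """
    if len(index) == 0:
        return 0
    k = int(np.searchsorted(index["first"], position, side="right")) - 1
    return int(index["offset"][max(k, 0)])


def _block_range(aln: Alignment, chrom: int, part: str, region: Region) -> tuple[int, int]:
    """Record range [lo, hi) covering all candidate blocks for a region."""
    index = aln.read_index(chrom, part)
    n = aln.count(chrom, part)
    if n == 0:
        return 0, 0
    lo = locate(index, region.start)
    k = int(np.searchsorted(index["first"], region.end, side="right"))
    hi = int(index["offset"][k]) if k < len(index) else n
    return lo, max(lo, hi)


@dataclass
class _Scan:
    lo: int
    mask: np.ndarray  # over decoded records [lo, lo+len(mask))
    pos: Optional[np.ndarray]
    attrs: Optional[np.ndarray]
    weights: Optional[np.ndarray]


def _selection(aln: Alignment, chrom: int, part: str, region: Optional[Region],
               filt: HitFilter, stats: Optional[QueryStats],
               need_weights: bool, need_pos: bool = False) -> _Scan:
    """Shared scan over the candidate block range.

    ``mask`` selects, among the decoded records, those inside the region
    and passing the filter.  Only the columns the filter and projection
    need are read from disk.
    """
    if region is None:
        lo, hi = 0, aln.count(chrom, part)
        pos = aln.read_positions(chrom, part, lo, hi) if need_pos else None
    else:
        lo, hi = _block_range(aln, chrom, part, region)
        pos = aln.read_positions(chrom, part, lo, hi)
    if stats is not None:
        stats.records_decoded += hi - lo
    if region is not None:
        mask = (pos >= region.start) & (pos <= region.end)
    else:
        mask = np.ones(hi - lo, dtype=bool)
    attrs = None
    if filt.strand != "both":
        attrs = aln.read_attrs(chrom, part, lo, hi)
        minus = (attrs & STRAND_BIT) != 0
        mask &= minus if filt.strand == "-" else ~minus
    weights = None
    if filt.minweight is not None or need_weights:
        weights = aln.read_weights(chrom, part, lo, hi)
        if filt.minweight is not None:
            mask &= weights >= np.float32(filt.minweight)
    return _Scan(lo, mask, pos, attrs, weights)


def get_hits(aln: Alignment, region: Region, filt: HitFilter = HitFilter(),
             projection: str = "full", stats: Optional[QueryStats] = None
             ) -> Union[HitArray, PairedHitArray, np.ndarray]:
    """Hits whose stored 5' position falls in ``region``, in position order.

    projection:
      - ``"full"``: a :class:`HitArray` (single-end) or
        :class:`PairedHitArray` (paired endedness);
      - ``"positions"``: just the int32 position array;
      - ``"weights"``: just the float32 weight array.
    """
    if projection not in ("full", "positions", "weights"):
        raise ValueError(f"unknown projection {projection!r}")
    part = filt.endedness
    scan = _selection(
        aln, part=part, chrom=region.chrom, region=region, filt=filt,
        stats=stats, need_weights=(projection in ("full", "weights")),
    )
    lo, hi = scan.lo, scan.lo + len(scan.mask)
    if projection == "positions":
        return scan.pos[scan.mask]
    if projection == "weights":
        return scan.weights[scan.mask]
    if part == SINGLE:
        attrs = scan.attrs if scan.attrs is not None else aln.read_attrs(region.chrom, part, lo, hi)
        return HitArray(scan.pos[scan.mask], attrs[scan.mask], scan.weights[scan.mask])
    return aln.read_paired(region.chrom, part, lo, hi).take(scan.mask)


def count_hits(aln: Alignment, region: Optional[Region] = None,
               chrom: Optional[int] = None, filt: HitFilter = HitFilter(),
               stats: Optional[QueryStats] = None) -> int:
    """Number of selected hits, without materialising them.

    With a region: hits in that interval.  With only ``chrom``: the whole
    chromosome.  With neither: the whole alignment.
    """
    if region is None and chrom is None:
        return sum(
            count_hits(aln, chrom=c, filt=filt, stats=stats)
            for c in aln.chroms()
        )
    c = region.chrom if region is not None else chrom
    if filt.strand == "both" and filt.minweight is None and region is None:
        return aln.count(c, filt.endedness)  # file size alone answers it
    scan = _selection(
        aln, chrom=c, part=filt.endedness, region=region, filt=filt,
        stats=stats, need_weights=False,
    )
    return int(scan.mask.sum())


def sum_weights(aln: Alignment, region: Optional[Region] = None,
                chrom: Optional[int] = None, filt: HitFilter = HitFilter(),
                stats: Optional[QueryStats] = None) -> float:
    """Sum of selected hit weights, accumulated in double precision."""
    if region is None and chrom is None:
        return float(sum(
            sum_weights(aln, chrom=c, filt=filt, stats=stats)
            for c in aln.chroms()
        ))
    c = region.chrom if region is not None else chrom
    scan = _selection(
        aln, chrom=c, part=filt.endedness, region=region, filt=filt,
        stats=stats, need_weights=True,
    )
    return float(scan.weights[scan.mask].astype(np.float64).sum())


def histogram(aln: Alignment, region: Region, binwidth: int, mode: str = "count",
              filt: HitFilter = HitFilter(), stats: Optional[QueryStats] = None
              ) -> Histogram:
    """Per-bin hit counts or weight sums across a region.

    Bins anchor at ``region.start``; a hit at position p contributes to
    the bin starting at ``start + binwidth * floor((p - start)/binwidth)``.
    Empty bins are omitted.  A count histogram's bin total equals
    :func:`count_hits` over the same region and filter; a weight
    histogram's total equals :func:`sum_weights`.
    """
    if binwidth < 1:
        raise ValueError(f"binwidth must be >= 1, got {binwidth}")
    if mode not in ("count", "weight"):
        raise ValueError(f"mode must be 'count' or 'weight', got {mode!r}")
    part = filt.endedness
    scan = _selection(
        aln, chrom=region.chrom, part=part, region=region, filt=filt,
        stats=stats, need_weights=(mode == "weight"),
    )
    mask = scan.mask
    pos = scan.pos[mask]
    binstarts = region.start + binwidth * ((pos.astype(np.int64) - region.start) // binwidth)
    bins: Dict[int, float] = {}
    if mode == "count":
        uniq, counts = np.unique(binstarts, return_counts=True)
        bins = {int(b): int(c) for b, c in zip(uniq, counts)}
    else:
        w = scan.weights[mask].astype(np.float64)
        uniq = np.unique(binstarts)
        sums = np.zeros(len(uniq))
        np.add.at(sums, np.searchsorted(uniq, binstarts), w)
        bins = {int(b): float(s) for b, s in zip(uniq, sums) if s > 0}
    return Histogram(region=region, binwidth=binwidth, mode=mode, bins=bins)


def list_chromosomes(aln: Alignment) -> Dict[int, Dict[str, int]]:
    """Chromosomes with >= 1 stored record in any partition, with counts."""
    return aln.chroms()
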