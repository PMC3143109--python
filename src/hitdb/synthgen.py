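"""Deterministic synthetic datasets with exact ground truth.

The generator draws a population of mapped reads — single-end reads with
optional multi-mapping (k alignments, each of weight 1/k) and read pairs
in FR orientation — and exposes every derived view of the same draw:

* the in-memory hit arrays per chromosome (what a store should contain),
* a brute-force :class:`Oracle` that answers any region/filter query by
  full scan, independent of the indexed query path,
* SAM and BED fixture text whose import reproduces the hits exactly.

Randomness comes from a single ``numpy.random.default_rng`` (PCG64)
seeded from the spec, so the same spec yields byte-identical fixtures on
every platform and run.

The generator emulates the *shape* of short-read alignment data — sorted
hit positions, strand mixture, multi-mapping weights, paired inserts —
not its biology: there are no error models, fragment-length biases, or
coverage hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .hitcore import (
    PAIRED_LEFT,
    PAIRED_RIGHT,
    SINGLE,
    STRAND_BIT,
    Histogram,
    HitArray,
    HitFilter,
    PairedHit,
    PairedHitArray,
    Region,
    pack_attrs,
)

__all__ = ["GenSpec", "Oracle", "SyntheticDataset", "generate", "gen_hits", "gen_sam", "gen_bed"]


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one synthetic read population.

    ``n_reads`` reads are drawn; a ``paired_fraction`` of them are read
    pairs (two ends each), the rest single-end.  Positions are uniform on
    ``[pos_min, pos_max]``.  ``weight_model``:

    * ``"unit"`` — every read aligns once, weight 1.0;
    * ``"multiplicity"`` — a read aligns k times (k in {1,2,4} with
      probability 0.7/0.2/0.1), yielding k hits of weight 1/k;
    * ``"uniform"`` — one alignment, weight uniform on [0.25, 2.0]
      (expressible in BED fixtures only, not SAM).
    """

    seed: int = 0
    n_reads: int = 1000
    n_chroms: int = 2
    pos_min: int = 1000
    pos_max: int = 1_000_000
    minus_fraction: float = 0.5
    read_length: int = 36
    weight_model: str = "unit"
    paired_fraction: float = 0.0
    insert_min: int = 100
    insert_max: int = 300
    interchrom_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if not 1 <= self.pos_min <= self.pos_max:
            raise ValueError("need 1 <= pos_min <= pos_max")
        if self.weight_model not in ("unit", "multiplicity", "uniform"):
            raise ValueError(f"unknown weight_model {self.weight_model!r}")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must be in [0, 1]")
        if self.insert_min < 2 or self.insert_min > self.insert_max:
            raise ValueError("need 2 <= insert_min <= insert_max")
        if self.pos_min <= self.read_length:
            raise ValueError("pos_min must exceed read_length (keeps spans on-chromosome)")


@dataclass
class _SingleRead:
    name: str
    chrom: int  # per-alignment chrom list below
    chroms: List[int]
    positions: List[int]  # 5' positions
    minus: List[bool]
    weight: float  # per-alignment weight

    @property
    def multiplicity(self) -> int:
        return len(self.positions)


@dataclass
class _Pair:
    name: str
    # left-anchored (left = smaller (chrom, pos) key)
    chrom: int
    pos: int
    minus: bool
    matechrom: int
    matepos: int
    mateminus: bool
    weight: float


class Oracle:
    """Brute-force ground truth: answers every query by a full scan of
    the generator's in-memory arrays, never touching an index or file."""

    def __init__(self, hits_by_chrom: Dict[int, HitArray],
                 pairs_left: Dict[int, PairedHitArray],
                 pairs_right: Dict[int, PairedHitArray]) -> None:
        self._single = hits_by_chrom
        self._parts = {SINGLE: None, PAIRED_LEFT: pairs_left, PAIRED_RIGHT: pairs_right}

    def _columns(self, chrom: int, part: str):
        """(pos, attrs, weight) arrays for one chrom+partition."""
        if part == SINGLE:
            h = self._single.get(chrom)
            if h is None:
                return None
            return h.pos, h.attrs, h.weight
        p = self._parts[part].get(chrom)
        if p is None:
            return None
        return p.pos, p.attrs, p.weight

    def chroms(self) -> Dict[int, Dict[str, int]]:
        out: Dict[int, Dict[str, int]] = {}
        for c, h in self._single.items():
            if len(h):
                out.setdefault(c, {p: 0 for p in (SINGLE, PAIRED_LEFT, PAIRED_RIGHT)})[SINGLE] = len(h)
        for part in (PAIRED_LEFT, PAIRED_RIGHT):
            for c, p in self._parts[part].items():
                if len(p):
                    out.setdefault(c, {q: 0 for q in (SINGLE, PAIRED_LEFT, PAIRED_RIGHT)})[part] = len(p)
        return {c: v for c, v in sorted(out.items())}

    def _mask(self, cols, region: Optional[Region], filt: HitFilter) -> np.ndarray:
        pos, attrs, weight = cols
        mask = np.ones(len(pos), dtype=bool)
        if region is not None:
            mask &= (pos >= region.start) & (pos <= region.end)
        if filt.strand != "both":
            minus = (attrs & STRAND_BIT) != 0
            mask &= minus if filt.strand == "-" else ~minus
        if filt.minweight is not None:
            mask &= weight >= np.float32(filt.minweight)
        return mask

    def count(self, region: Optional[Region] = None, chrom: Optional[int] = None,
              filt: HitFilter = HitFilter()) -> int:
        if region is None and chrom is None:
            return sum(self.count(chrom=c, filt=filt) for c in self.chroms())
        c = region.chrom if region is not None else chrom
        cols = self._columns(c, filt.endedness)
        return 0 if cols is None else int(self._mask(cols, region, filt).sum())

    def weight_sum(self, region: Optional[Region] = None, chrom: Optional[int] = None,
                   filt: HitFilter = HitFilter()) -> float:
        if region is None and chrom is None:
            return float(sum(self.weight_sum(chrom=c, filt=filt) for c in self.chroms()))
        c = region.chrom if region is not None else chrom
        cols = self._columns(c, filt.endedness)
        if cols is None:
            return 0.0
        mask = self._mask(cols, region, filt)
        return float(cols[2][mask].astype(np.float64).sum())

    def positions(self, region: Region, filt: HitFilter = HitFilter()) -> np.ndarray:
        cols = self._columns(region.chrom, filt.endedness)
        if cols is None:
            return np.empty(0, dtype=np.int32)
        mask = self._mask(cols, region, filt)
        return np.sort(cols[0][mask])

    def histogram(self, region: Region, binwidth: int, mode: str = "count",
                  filt: HitFilter = HitFilter()) -> Histogram:
        cols = self._columns(region.chrom, filt.endedness)
        bins: Dict[int, float] = {}
        if cols is not None:
            mask = self._mask(cols, region, filt)
            pos = cols[0][mask]
            w = cols[2][mask].astype(np.float64)
            for p, wi in zip(pos.tolist(), w.tolist()):
                b = region.start + binwidth * ((p - region.start) // binwidth)
                bins[b] = bins.get(b, 0) + (1 if mode == "count" else wi)
        return Histogram(region=region, binwidth=binwidth, mode=mode,
                         bins={b: v for b, v in bins.items() if v > 0})


class SyntheticDataset:
    """One realised draw: reads, derived hit arrays, and the oracle."""

    def __init__(self, spec: GenSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.chrom_names = {f"chr{c}": c for c in range(1, spec.n_chroms + 1)}
        self._singles: List[_SingleRead] = []
        self._pairs: List[_Pair] = []
        n_paired = int(round(spec.n_reads * spec.paired_fraction))
        n_single = spec.n_reads - n_paired
        for i in range(n_single):
            name = f"s{i:07d}"
            if spec.weight_model == "multiplicity":
                k = int(rng.choice([1, 2, 4], p=[0.7, 0.2, 0.1]))
                weight = 1.0 / k
            else:
                k = 1
                weight = (float(np.float32(rng.uniform(0.25, 2.0)))
                          if spec.weight_model == "uniform" else 1.0)
            chroms = rng.integers(1, spec.n_chroms + 1, size=k).tolist()
            positions = rng.integers(spec.pos_min, spec.pos_max + 1, size=k).tolist()
            minus = (rng.random(k) < spec.minus_fraction).tolist()
            self._singles.append(_SingleRead(name, chroms[0], chroms, positions, minus, weight))
        L = spec.read_length
        for i in range(n_paired):
            name = f"p{i:07d}"
            c = int(rng.integers(1, spec.n_chroms + 1))
            p1 = int(rng.integers(spec.pos_min, spec.pos_max + 1))
            if spec.interchrom_fraction and rng.random() < spec.interchrom_fraction and spec.n_chroms > 1:
                c2 = int(rng.choice([x for x in range(1, spec.n_chroms + 1) if x != c]))
                p2 = int(rng.integers(spec.pos_min, spec.pos_max + 1))
                end1 = (c, p1, False)   # + strand end
                end2 = (c2, p2, True)   # - strand end, 5' pos
            else:
                insert = int(rng.integers(spec.insert_min, spec.insert_max + 1))
                end1 = (c, p1, False)
                end2 = (c, p1 + insert - 1, True)
            # left = smaller (chrom, 5'-pos) key; tie broken + first
            k1 = (end1[0], end1[1], 0 if not end1[2] else 1)
            k2 = (end2[0], end2[1], 0 if not end2[2] else 1)
            left, right = (end1, end2) if k1 <= k2 else (end2, end1)
            self._pairs.append(_Pair(name, left[0], left[1], left[2],
                                     right[0], right[1], right[2], 1.0))

        self.hits_by_chrom = self._build_single_arrays()
        self.pairs = self._build_pair_array()
        left_by, right_by = self._pair_partitions()
        self.oracle = Oracle(self.hits_by_chrom, left_by, right_by)

    # -- derived views -------------------------------------------------

    def _build_single_arrays(self) -> Dict[int, HitArray]:
        by: Dict[int, List[tuple[int, bool, float]]] = {}
        for r in self._singles:
            for c, p, m in zip(r.chroms, r.positions, r.minus):
                by.setdefault(c, []).append((p, m, r.weight))
        out: Dict[int, HitArray] = {}
        L = self.spec.read_length
        for c, rows in by.items():
            pos = np.array([r[0] for r in rows])
            minus = np.array([r[1] for r in rows])
            w = np.array([r[2] for r in rows])
            out[c] = HitArray(pos, pack_attrs(minus, np.full(len(rows), L)), w)
        return out

    def _build_pair_array(self) -> PairedHitArray:
        """All pairs, anchored on their left end."""
        L = self.spec.read_length
        n = len(self._pairs)
        return PairedHitArray(
            [p.chrom for p in self._pairs],
            [p.pos for p in self._pairs],
            pack_attrs([p.minus for p in self._pairs], np.full(n, L)),
            [p.weight for p in self._pairs],
            [p.matechrom for p in self._pairs],
            [p.matepos for p in self._pairs],
            pack_attrs([p.mateminus for p in self._pairs], np.full(n, L)),
        )

    def _pair_partitions(self) -> tuple[Dict[int, PairedHitArray], Dict[int, PairedHitArray]]:
        left_by: Dict[int, PairedHitArray] = {}
        right_by: Dict[int, PairedHitArray] = {}
        pairs = self.pairs
        flipped = pairs.flipped()
        for c in np.unique(pairs.chrom):
            left_by[int(c)] = pairs.take(pairs.chrom == c)
        for c in np.unique(flipped.chrom):
            right_by[int(c)] = flipped.take(flipped.chrom == c)
        return left_by, right_by

    def paired_hits(self) -> List[PairedHit]:
        return self.pairs.to_pairs()

    # -- fixture emission ----------------------------------------------

    def sam_text(self) -> str:
        """Minimal valid SAM whose import reproduces this dataset exactly.

        Multi-mapping reads carry NH tags and secondary flags; pairs are
        emitted FR with mate coordinates.  Arbitrary per-hit weights
        (``weight_model="uniform"``) cannot be expressed in SAM — use
        :meth:`bed_text` for those fixtures.
        """
        if self.spec.weight_model == "uniform":
            raise ValueError("uniform per-hit weights are not expressible in SAM; use bed_text()")
        L = self.spec.read_length
        sqlen = self.spec.pos_max + self.spec.insert_max + 2 * L
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        for name, _c in self.chrom_names.items():
            lines.append(f"@SQ\tSN:{name}\tLN:{sqlen}")
        names = {c: n for n, c in self.chrom_names.items()}
        for r in self._singles:
            k = r.multiplicity
            for j, (c, p, m) in enumerate(zip(r.chroms, r.positions, r.minus)):
                flag = (16 if m else 0) | (256 if j > 0 else 0)
                pos0 = p - L + 1 if m else p  # SAM POS = leftmost aligned base
                lines.append(
                    f"{r.name}\t{flag}\t{names[c]}\t{pos0}\t255\t{L}M\t*\t0\t0\t*\t*\tNH:i:{k}"
                )
        for p in self._pairs:
            intra = p.chrom == p.matechrom
            lpos0 = p.pos - L + 1 if p.minus else p.pos
            rpos0 = p.matepos - L + 1 if p.mateminus else p.matepos
            lflag = 1 | 64 | (16 if p.minus else 0) | (32 if p.mateminus else 0)
            rflag = 1 | 128 | (16 if p.mateminus else 0) | (32 if p.minus else 0)
            if intra:
                lflag |= 2
                rflag |= 2
                span_lo = min(lpos0, rpos0)
                span_hi = max(lpos0 + L - 1, rpos0 + L - 1)
                tlen = span_hi - span_lo + 1
                ltlen, rtlen = (tlen, -tlen) if lpos0 <= rpos0 else (-tlen, tlen)
                rnext_l = rnext_r = "="
            else:
                ltlen = rtlen = 0
                rnext_l, rnext_r = names[p.matechrom], names[p.chrom]
            lines.append(
                f"{p.name}\t{lflag}\t{names[p.chrom]}\t{lpos0}\t255\t{L}M\t{rnext_l}\t{rpos0}\t{ltlen}\t*\t*\tNH:i:1"
            )
            lines.append(
                f"{p.name}\t{rflag}\t{names[p.matechrom]}\t{rpos0}\t255\t{L}M\t{rnext_r}\t{lpos0}\t{rtlen}\t*\t*\tNH:i:1"
            )
        return "\n".join(lines) + "\n"

    def bed_text(self) -> str:
        """BED6 fixture for the single-end hits; the score column carries
        each hit's weight."""
        L = self.spec.read_length
        names = {c: n for n, c in self.chrom_names.items()}
        lines = []
        for r in self._singles:
            for j, (c, p, m) in enumerate(zip(r.chroms, r.positions, r.minus)):
                start0 = p - L if m else p - 1
                end0 = p if m else p + L - 1
                strand = "-" if m else "+"
                w = repr(float(np.float32(r.weight)))
                lines.append(f"{names[c]}\t{start0}\t{end0}\t{r.name}.{j}\t{w}\t{strand}")
        return "\n".join(lines) + ("\n" if lines else "")


def generate(spec: GenSpec) -> SyntheticDataset:
    """Materialise a dataset for a spec (deterministic in the seed)."""
    return SyntheticDataset(spec)


def gen_hits(spec: GenSpec) -> tuple[Dict[int, HitArray], Oracle]:
    """Single-end hits per chromosome, plus the full brute-force oracle."""
    ds = generate(spec)
    return ds.hits_by_chrom, ds.oracle


def gen_sam(spec: GenSpec, path: Optional[Union[str, Path]] = None) -> str:
    """SAM fixture text; optionally written to ``path``."""
    text = generate(spec).sam_text()
    if path is not None:
        Path(path).write_text(text)
    return text


def gen_bed(spec: GenSpec, path: Optional[Union[str, Path]] = None) -> str:
    """BED fixture text; optionally written to ``path``."""
    text = generate(spec).bed_text()
    if path is not None:
        Path(path).write_text(text)
    return text
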