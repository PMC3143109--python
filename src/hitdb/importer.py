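"""Convert SAM/BAM and BED alignments into stored hits.

Each mapped record becomes a hit at the read's 5' position: the leftmost
aligned base for a forward-strand alignment, the rightmost for reverse.
The hit length is the reference-consuming span of the alignment (so
spliced or gapped alignments get their genomic extent, not the read
length).  The hit weight is 1/k for a read with k alignments — from the
standard NH tag when present, otherwise by counting records per read
name — so every read contributes total mass 1 regardless of
multi-mapping.

Chromosome names are mapped to the store's integer ids through a
persistent two-column sidecar (``chrommap.tsv``); re-importing into the
same alignment reuses existing ids, so stores stay stable across
imports.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pysam

from .columnstore import Alignment
from .hitcore import (
    MAX_LENGTH,
    HitArray,
    PairedHit,
    PairedHitArray,
    SingleHit,
)

__all__ = [
    "ChromMap",
    "ImportReport",
    "import_sam",
    "import_bed",
    "sam_to_hits",
    "sam_to_pairs",
    "bed_to_hits",
]

log = logging.getLogger(__name__)


class ChromMap:
    """Bijective chromosome-name <-> integer-id table.

    Ids are assigned on demand starting after the largest existing id;
    the table persists as the alignment's ``chrommap.tsv`` sidecar and is
    reused by later imports, so a name maps to the same id forever.
    """

    def __init__(self, mapping: Optional[Dict[str, int]] = None) -> None:
        self._by_name: Dict[str, int] = dict(mapping or {})
        self._by_id: Dict[int, str] = {v: k for k, v in self._by_name.items()}
        if len(self._by_id) != len(self._by_name):
            raise ValueError("chromosome map is not bijective")

    @classmethod
    def load(cls, aln: Alignment) -> "ChromMap":
        return cls(aln.load_chrommap())

    def save(self, aln: Alignment) -> None:
        aln.save_chrommap(self._by_name)

    def id_for(self, name: str) -> int:
        if name not in self._by_name:
            cid = max(self._by_id, default=0) + 1
            self._by_name[name] = cid
            self._by_id[cid] = name
        return self._by_name[name]

    def name_for(self, cid: int) -> str:
        return self._by_id[cid]

    def get_id(self, name: str) -> Optional[int]:
        return self._by_name.get(name)

    def as_dict(self) -> Dict[str, int]:
        return dict(self._by_name)

    def __len__(self) -> int:
        return len(self._by_name)


@dataclass
class ImportReport:
    """Tally of one import run."""

    records_read: int = 0
    hits_imported: int = 0
    pairs_imported: int = 0
    skipped_unmapped: int = 0
    skipped_long: int = 0
    skipped_supplementary: int = 0
    orphan_mates: int = 0
    malformed: int = 0

    def summary(self) -> str:
        return (
            f"read={self.records_read} hits={self.hits_imported} "
            f"pairs={self.pairs_imported} unmapped={self.skipped_unmapped} "
            f"too_long={self.skipped_long} supplementary={self.skipped_supplementary} "
            f"orphans={self.orphan_mates} malformed={self.malformed}"
        )


@dataclass
class _Rec:
    """The slice of a SAM record the store keeps."""

    name: str
    chrom: int
    fivepos: int
    minus: bool
    length: int
    nh: Optional[int]
    is_paired: bool
    is_read1: bool
    leftpos: int       # 1-based leftmost, for mate joining
    mate_chrom: int = -1
    mate_leftpos: int = -1


def _five_prime(leftmost1: int, span: int, minus: bool) -> int:
    return leftmost1 + span - 1 if minus else leftmost1


def _scan_sam(path: Union[str, Path], chrommap: ChromMap,
              report: ImportReport) -> Tuple[List[_Rec], List[_Rec]]:
    """First pass: decode the fields we keep; returns (single, paired) records."""
    singles: List[_Rec] = []
    paired: List[_Rec] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        # Assign ids for header sequences in header order so stores built
        # from the same reference dictionary are comparable.
        for sq in af.references or ():
            chrommap.id_for(sq)
        for rec in af:
            report.records_read += 1
            if rec.is_unmapped or rec.reference_id < 0:
                report.skipped_unmapped += 1
                continue
            if rec.is_supplementary:
                report.skipped_supplementary += 1
                continue
            span = rec.reference_length or 0
            if span < 1:
                report.malformed += 1
                continue
            if span > MAX_LENGTH:
                report.skipped_long += 1
                log.warning("record %s: span %d exceeds the 15-bit length field; skipped",
                            rec.query_name, span)
                continue
            left1 = rec.reference_start + 1
            r = _Rec(
                name=rec.query_name or "",
                chrom=chrommap.id_for(af.get_reference_name(rec.reference_id)),
                fivepos=_five_prime(left1, span, rec.is_reverse),
                minus=rec.is_reverse,
                length=span,
                nh=rec.get_tag("NH") if rec.has_tag("NH") else None,
                is_paired=rec.is_paired,
                is_read1=not rec.is_paired or rec.is_read1,
                leftpos=left1,
            )
            if r.is_paired:
                if rec.mate_is_unmapped or rec.next_reference_id < 0:
                    report.orphan_mates += 1
                    continue
                r.mate_chrom = chrommap.id_for(af.get_reference_name(rec.next_reference_id))
                r.mate_leftpos = rec.next_reference_start + 1
                paired.append(r)
            else:
                singles.append(r)
    return singles, paired


def _single_hits(records: List[_Rec]) -> List[Tuple[int, SingleHit]]:
    """Weighted hits from single-end records: weight 1/k per alignment."""
    counts: Dict[str, int] = defaultdict(int)
    need_count = any(r.nh is None for r in records)
    if need_count:
        for r in records:
            counts[r.name] += 1
    out: List[Tuple[int, SingleHit]] = []
    for r in records:
        k = r.nh if r.nh is not None else counts[r.name]
        out.append((r.chrom, SingleHit(
            chrom=r.chrom, pos=r.fivepos,
            strand="-" if r.minus else "+",
            length=r.length, weight=1.0 / max(k, 1),
        )))
    return out


def _join_pairs(records: List[_Rec], report: ImportReport) -> List[PairedHit]:
    """Join mates by read name; left = smaller (chrom, 5'-pos) key, ties
    broken by strand (+ first).  Pair weight is 1/(pair alignments)."""
    by_name: Dict[str, List[_Rec]] = defaultdict(list)
    for r in records:
        by_name[r.name].append(r)
    pairs: List[PairedHit] = []
    for name, group in by_name.items():
        firsts = [r for r in group if r.is_read1]
        seconds = [r for r in group if not r.is_read1]
        matched: List[Tuple[_Rec, _Rec]] = []
        used = [False] * len(seconds)
        for a in firsts:
            hit_idx = None
            for j, b in enumerate(seconds):
                if used[j]:
                    continue
                if (a.mate_chrom == b.chrom and a.mate_leftpos == b.leftpos
                        and b.mate_chrom == a.chrom and b.mate_leftpos == a.leftpos):
                    hit_idx = j
                    break
            if hit_idx is None:
                report.orphan_mates += 1
                continue
            used[hit_idx] = True
            matched.append((a, seconds[hit_idx]))
        report.orphan_mates += used.count(False)
        if not matched:
            continue
        k = matched[0][0].nh if matched[0][0].nh is not None else len(matched)
        w = 1.0 / max(k, 1)
        for a, b in matched:
            ka = (a.chrom, a.fivepos, 1 if a.minus else 0)
            kb = (b.chrom, b.fivepos, 1 if b.minus else 0)
            left, right = (a, b) if ka <= kb else (b, a)
            pairs.append(PairedHit(
                chrom=left.chrom, pos=left.fivepos,
                strand="-" if left.minus else "+", length=left.length, weight=w,
                matechrom=right.chrom, matepos=right.fivepos,
                matestrand="-" if right.minus else "+", matelength=right.length,
            ))
    return pairs


def sam_to_hits(path: Union[str, Path], chrommap: Optional[ChromMap] = None,
                report: Optional[ImportReport] = None) -> List[SingleHit]:
    """Single-end hits of a SAM/BAM file (paired records are ignored here)."""
    chrommap = chrommap or ChromMap()
    report = report or ImportReport()
    singles, _paired = _scan_sam(path, chrommap, report)
    return [h for _c, h in _single_hits(singles)]

def sam_to_pairs(path: Union[str, Path], chrommap: Optional[ChromMap] = None,
                 report: Optional[ImportReport] = None) -> List[PairedHit]:
    """Joined read pairs of a SAM/BAM file, anchored on their left end."""
    chrommap = chrommap or ChromMap()
    report = report or ImportReport()
    _singles, paired = _scan_sam(path, chrommap, report)
    return _join_pairs(paired, report)


def bed_to_hits(path: Union[str, Path], chrommap: Optional[ChromMap] = None,
                report: Optional[ImportReport] = None) -> List[SingleHit]:
    """Hits from a BED3+ file.

    BED is 0-based half-open: length = chromEnd - chromStart; the 5'
    position is chromStart+1 on ``+`` and chromEnd on ``-`` (missing
    strand column means ``+``).  The score column becomes the weight when
    it parses as a finite number > 0, else 1.0.
    """
    chrommap = chrommap or ChromMap()
    report = report or ImportReport()
    hits: List[SingleHit] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        report.records_read += 1
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start0, end0 = int(f[1]), int(f[2])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
        length = end0 - start0
        if length < 1:
            report.malformed += 1
            continue
        if length > MAX_LENGTH:
            report.skipped_long += 1
            continue
        strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "+"
        weight = 1.0
        if len(f) >= 5:
            try:
                sc = float(f[4])
                if sc > 0 and sc != float("inf"):
                    weight = sc
            except ValueError:
                pass
        pos = start0 + 1 if strand == "+" else end0
        hits.append(SingleHit(
            chrom=chrommap.id_for(f[0]), pos=pos, strand=strand,
            length=length, weight=weight,
        ))
    return hits


def _store_hits(aln: Alignment, hits: Iterable[SingleHit]) -> int:
    by_chrom: Dict[int, List[SingleHit]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chrom].append(h)
    n = 0
    for chrom, hs in sorted(by_chrom.items()):
        aln.append_single(chrom, HitArray.from_hits(hs))
        n += len(hs)
    return n


def import_sam(path: Union[str, Path], aln: Alignment) -> ImportReport:
    """Import a SAM/BAM file into an alignment directory.

    Single-end records go to the single partitions; paired records are
    mate-joined and stored twice (left- and right-keyed).  The chromosome
    map sidecar is updated in place.
    """
    report = ImportReport()
    chrommap = ChromMap.load(aln)
    singles, paired = _scan_sam(path, chrommap, report)
    report.hits_imported = _store_hits(aln, (h for _c, h in _single_hits(singles)))
    pairs = _join_pairs(paired, report)
    if pairs:
        aln.append_paired(PairedHitArray.from_pairs(pairs))
    report.pairs_imported = len(pairs)
    chrommap.save(aln)
    log.info("imported %s: %s", path, report.summary())
    return report


def import_bed(path: Union[str, Path], aln: Alignment) -> ImportReport:
    """Import a BED file into an alignment directory (single-end only)."""
    report = ImportReport()
    chrommap = ChromMap.load(aln)
    hits = bed_to_hits(path, chrommap, report)
    report.hits_imported = _store_hits(aln, hits)
    chrommap.save(aln)
    log.info("imported %s: %s", path, report.summary())
    return report
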