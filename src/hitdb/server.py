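"""Line-oriented TCP server exposing the store and query operations.

The wire protocol is plain UTF-8 text so any language can speak it
(docs/PROTOCOL.md gives the full grammar).  One request is one line:

    VERB key=value key=value ...

``STORE``/``STOREPAIRED`` requests are followed by ``count`` tab-separated
data lines.  Every response starts with a status line — ``OK <n>`` with
``n`` payload lines to follow, or ``ERROR <code> <message>`` — and the
connection stays open for further requests; a malformed request never
ends the session.

Concurrency contract: many readers, single writer per alignment.  Writes
take an exclusive per-alignment lock; readers take the same lock briefly
so they never observe a half-rewritten partition.  A shared, mtime-
validated index cache lets repeated region queries skip re-reading index
files.
"""

from __future__ import annotations

import logging
import re
import socketserver
import threading
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .columnstore import Alignment, IndexCache, StoreNotFoundError
from .hitcore import (
    PAIRED_LEFT,
    PAIRED_RIGHT,
    SINGLE,
    CorruptRecordError,
    HitArray,
    HitFilter,
    HitRangeError,
    PairedHitArray,
    Region,
    pack_strand_length,
    unpack_strand_length,
)
from . import query as q

__all__ = ["HitDBServer", "DEFAULT_PORT"]

log = logging.getLogger(__name__)

DEFAULT_PORT = 52734

_ALIGN_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._-]*$")

VERBS = (
    "STORE", "STOREPAIRED", "DELETE", "CHROMS", "COUNT",
    "WEIGHTSUM", "GETHITS", "HISTOGRAM", "SHUTDOWN", "BYE",
)


class _ProtocolError(Exception):
    def __init__(self, code: int, message: str) -> None:
        super().__init__(message)
        self.code = code


def _fmt_weight(w: float) -> str:
    # shortest decimal that round-trips through float32
    return repr(float(np.float32(w)))


def _parse_request(line: str) -> tuple[str, Dict[str, str]]:
    tokens = line.split()
    if not tokens:
        raise _ProtocolError(400, "empty request")
    verb = tokens[0].upper()
    if verb not in VERBS:
        raise _ProtocolError(400, "unknown verb")
    params: Dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" not in tok:
            raise _ProtocolError(400, f"malformed parameter {tok!r}")
        key, value = tok.split("=", 1)
        params[key.lower()] = value
    return verb, params


def _need(params: Dict[str, str], key: str) -> str:
    if key not in params:
        raise _ProtocolError(400, f"missing parameter {key}")
    return params[key]


def _int_param(params: Dict[str, str], key: str, default=None) -> Optional[int]:
    if key not in params:
        if default is None:
            raise _ProtocolError(400, f"missing parameter {key}")
        return default
    try:
        return int(params[key])
    except ValueError:
        raise _ProtocolError(400, f"parameter {key} must be an integer")


def _filter_from(params: Dict[str, str]) -> HitFilter:
    strand = params.get("strand", "both")
    endedness = params.get("endedness", SINGLE)
    minweight = None
    if "minweight" in params:
        try:
            minweight = float(params["minweight"])
        except ValueError:
            raise _ProtocolError(400, "minweight must be a number")
    try:
        return HitFilter(strand=strand, minweight=minweight, endedness=endedness)
    except ValueError as e:
        raise _ProtocolError(400, str(e))


class _Handler(socketserver.StreamRequestHandler):
    server: "_TCPServer"

    def handle(self) -> None:
        while True:
            raw = self.rfile.readline()
            if not raw:
                return
            try:
                line = raw.decode("utf-8", errors="strict").rstrip("\r\n")
            except UnicodeDecodeError:
                self._respond_error(400, "request is not valid UTF-8")
                continue
            try:
                verb, params = _parse_request(line)
                if verb == "BYE":
                    self._respond("OK 0", [])
                    return
                payload = self._dispatch(verb, params)
            except _ProtocolError as e:
                self._respond_error(e.code, str(e))
                continue
            except StoreNotFoundError as e:
                self._respond_error(404, f"alignment not found: {e}")
                continue
            except (HitRangeError, CorruptRecordError, ValueError, IndexError) as e:
                self._respond_error(400, str(e))
                continue
            except Exception as e:  # noqa: BLE001 — the server must not crash
                log.exception("internal error handling %r", line)
                self._respond_error(500, f"internal error: {e}")
                continue
            self._respond(f"OK {len(payload)}", payload)
            if verb == "SHUTDOWN":
                threading.Thread(target=self.server.hitdb.shutdown, daemon=True).start()
                return

    def _respond(self, status: str, payload: List[str]) -> None:
        out = status + "\n" + "".join(p + "\n" for p in payload)
        self.wfile.write(out.encode("utf-8"))
        self.wfile.flush()

    def _respond_error(self, code: int, message: str) -> None:
        message = message.replace("\n", " ")
        self._respond(f"ERROR {code} {message}", [])

    # -- dispatch ------------------------------------------------------

    def _dispatch(self, verb: str, params: Dict[str, str]) -> List[str]:
        hitdb = self.server.hitdb
        if verb == "SHUTDOWN":
            return []
        align = _need(params, "align")
        if not _ALIGN_RE.match(align):
            raise _ProtocolError(400, f"invalid alignment name {align!r}")
        if verb == "STORE":
            return self._handle_store(align, params)
        if verb == "STOREPAIRED":
            return self._handle_store_paired(align, params)
        with hitdb.lock_for(align):
            if verb == "DELETE":
                aln = hitdb.open(align)
                endedness = params.get("endedness", "both")
                chrom = _int_param(params, "chrom", default=-1)
                aln.delete(None if chrom == -1 else chrom, endedness)
                return []
            aln = hitdb.open(align)
            if verb == "CHROMS":
                return [
                    f"{c}\t{v[SINGLE]}\t{v[PAIRED_LEFT]}\t{v[PAIRED_RIGHT]}"
                    for c, v in q.list_chromosomes(aln).items()
                ]
            filt = _filter_from(params)
            region = None
            chrom = _int_param(params, "chrom", default=-1)
            chrom = None if chrom == -1 else chrom
            if "start" in params or "end" in params:
                if chrom is None:
                    raise _ProtocolError(400, "region query requires chrom")
                region = Region(chrom, _int_param(params, "start"), _int_param(params, "end"))
            if verb == "COUNT":
                return [str(q.count_hits(aln, region=region, chrom=chrom, filt=filt))]
            if verb == "WEIGHTSUM":
                return [repr(q.sum_weights(aln, region=region, chrom=chrom, filt=filt))]
            if verb == "GETHITS":
                if region is None:
                    raise _ProtocolError(400, "GETHITS requires chrom, start, end")
                return self._format_hits(aln, region, filt, params.get("projection", "full"))
            if verb == "HISTOGRAM":
                if region is None:
                    raise _ProtocolError(400, "HISTOGRAM requires chrom, start, end")
                binwidth = _int_param(params, "binwidth")
                mode = params.get("mode", "count")
                hist = q.histogram(aln, region, binwidth, mode=mode, filt=filt)
                fmt = (lambda v: str(int(v))) if mode == "count" else repr
                return [f"{b}\t{fmt(v)}" for b, v in sorted(hist.bins.items())]
        raise _ProtocolError(400, "unknown verb")

    def _format_hits(self, aln: Alignment, region: Region, filt: HitFilter,
                     projection: str) -> List[str]:
        result = q.get_hits(aln, region, filt, projection=projection)
        if projection == "positions":
            return [str(p) for p in result.tolist()]
        if projection == "weights":
            return [_fmt_weight(w) for w in result.tolist()]
        if filt.endedness == SINGLE:
            out = []
            for pos, attrs, w in result:
                strand, length = unpack_strand_length(attrs)
                out.append(f"{pos}\t{strand}\t{length}\t{_fmt_weight(w)}")
            return out
        out = []
        for p in result.to_pairs():
            out.append(
                f"{p.pos}\t{p.strand}\t{p.length}\t{_fmt_weight(p.weight)}"
                f"\t{p.matechrom}\t{p.matepos}\t{p.matestrand}\t{p.matelength}"
            )
        return out

    # -- stores --------------------------------------------------------

    def _read_data_lines(self, n: int) -> List[str]:
        lines = []
        for i in range(n):
            raw = self.rfile.readline()
            if not raw:
                raise _ProtocolError(400, f"connection closed after {i} of {n} data lines")
            lines.append(raw.decode("utf-8").rstrip("\r\n"))
        return lines

    def _handle_store(self, align: str, params: Dict[str, str]) -> List[str]:
        chrom = _int_param(params, "chrom")
        n = _int_param(params, "count")
        if n < 0:
            raise _ProtocolError(400, "count must be >= 0")
        lines = self._read_data_lines(n)
        # Parse everything before touching disk: a failure on line k
        # persists nothing.
        pos, attrs, weights = [], [], []
        for i, line in enumerate(lines, start=1):
            f = line.split("\t")
            if len(f) != 4:
                raise _ProtocolError(400, f"data line {i}: expected 4 fields, got {len(f)}")
            try:
                p = int(f[0])
                word = pack_strand_length(f[1], int(f[2]))
                w = float(f[3])
            except (ValueError, HitRangeError) as e:
                raise _ProtocolError(400, f"data line {i}: {e}")
            pos.append(p)
            attrs.append(word)
            weights.append(w)
        hits = HitArray(pos, attrs, weights)
        hits.validate()
        hitdb = self.server.hitdb
        with hitdb.lock_for(align):
            hitdb.open(align, create=True).append_single(chrom, hits)
        return []

    def _handle_store_paired(self, align: str, params: Dict[str, str]) -> List[str]:
        n = _int_param(params, "count")
        if n < 0:
            raise _ProtocolError(400, "count must be >= 0")
        lines = self._read_data_lines(n)
        cols = ([], [], [], [], [], [], [])  # chrom,pos,attrs,weight,matechrom,matepos,mateattrs
        for i, line in enumerate(lines, start=1):
            f = line.split("\t")
            if len(f) != 9:
                raise _ProtocolError(400, f"data line {i}: expected 9 fields, got {len(f)}")
            try:
                vals = (
                    int(f[0]), int(f[1]), pack_strand_length(f[2], int(f[3])), float(f[4]),
                    int(f[5]), int(f[6]), pack_strand_length(f[7], int(f[8])),
                )
            except (ValueError, HitRangeError) as e:
                raise _ProtocolError(400, f"data line {i}: {e}")
            for col, v in zip(cols, vals):
                col.append(v)
        pairs = PairedHitArray(*cols)
        hitdb = self.server.hitdb
        with hitdb.lock_for(align):
            hitdb.open(align, create=True).append_paired(pairs)
        return []


class _TCPServer(socketserver.ThreadingTCPServer):
    allow_reuse_address = True
    daemon_threads = True
    hitdb: "HitDBServer"


class HitDBServer:
    """The server process object: owns the data root, the per-alignment
    locks, and the shared index cache."""

    def __init__(self, root, host: str = "127.0.0.1", port: int = 0) -> None:
        self.root = Path(root)
        if not self.root.is_dir():
            raise StoreNotFoundError(str(self.root))
        self.cache = IndexCache()
        self._locks: Dict[str, threading.RLock] = defaultdict(threading.RLock)
        self._locks_guard = threading.Lock()
        self._tcp = _TCPServer((host, port), _Handler)
        self._tcp.hitdb = self

    @property
    def address(self) -> tuple[str, int]:
        return self._tcp.server_address[:2]

    def lock_for(self, align: str) -> threading.RLock:
        with self._locks_guard:
            return self._locks[align]

    def open(self, align: str, create: bool = False) -> Alignment:
        return Alignment(self.root / align, create=create, index_cache=self.cache)

    def serve_forever(self) -> None:
        log.info("serving %s on %s:%d", self.root, *self.address)
        self._tcp.serve_forever()

    def start_background(self) -> threading.Thread:
        t = threading.Thread(target=self.serve_forever, daemon=True)
        t.start()
        return t

    def shutdown(self) -> None:
        self._tcp.shutdown()
        self._tcp.server_close()

    def __enter__(self) -> "HitDBServer":
        self.start_background()
        return self

    def __exit__(self, *exc) -> None:
        self.shutdown()
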