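"""Socket client mirroring the full server interface.

Each method issues exactly one protocol request and parses one response
into the core hit types; there is no client-side caching (the server's
index cache is the performance feature, the client stays a thin typed
wrapper).  Host and port default from the ``HITDB_HOST`` / ``HITDB_PORT``
environment variables.
"""

from __future__ import annotations

import os
import socket
from typing import Dict, List, Optional, Union

import numpy as np

from .hitcore import (
    PAIRED_LEFT,
    PAIRED_RIGHT,
    SINGLE,
    Histogram,
    PairedHit,
    Region,
    SingleHit,
)
from .server import DEFAULT_PORT

__all__ = ["Connection", "RemoteError", "NotFoundError"]


class RemoteError(Exception):
    """The server answered with an ERROR status."""

    def __init__(self, code: int, message: str) -> None:
        super().__init__(f"{code} {message}")
        self.code = code
        self.message = message


class NotFoundError(RemoteError):
    """ERROR 404: the alignment (or resource) does not exist."""


def _fmt_weight(w: float) -> str:
    return repr(float(np.float32(w)))


class Connection:
    """A live connection to a hit-store server.

    Use as a context manager or call :meth:`close`; any operation on a
    closed connection raises ``ConnectionError`` rather than hanging.
    """

    def __init__(self, host: Optional[str] = None, port: Optional[int] = None,
                 timeout: Optional[float] = None) -> None:
        self.host = host or os.environ.get("HITDB_HOST", "127.0.0.1")
        self.port = int(port if port is not None else os.environ.get("HITDB_PORT", DEFAULT_PORT))
        self._sock = socket.create_connection((self.host, self.port), timeout=timeout)
        self._io = self._sock.makefile("rwb")

    # -- plumbing ------------------------------------------------------

    def close(self) -> None:
        if self._io is not None:
            try:
                self._io.close()
            finally:
                self._sock.close()
                self._io = None

    def __enter__(self) -> "Connection":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _request(self, verb: str, params: Dict[str, object],
                 data_lines: Optional[List[str]] = None) -> List[str]:
        if self._io is None:
            raise ConnectionError("connection is closed")
        parts = [verb] + [f"{k}={v}" for k, v in params.items() if v is not None]
        msg = " ".join(parts) + "\n"
        if data_lines:
            msg += "".join(line + "\n" for line in data_lines)
        self._io.write(msg.encode("utf-8"))
        self._io.flush()
        status = self._io.readline()
        if not status:
            raise ConnectionError("server closed the connection")
        fields = status.decode("utf-8").rstrip("\n").split(" ", 2)
        if fields[0] == "OK":
            n = int(fields[1])
            payload = []
            for _ in range(n):
                line = self._io.readline()
                if not line:
                    raise ConnectionError("connection closed mid-payload")
                payload.append(line.decode("utf-8").rstrip("\n"))
            return payload
        if fields[0] == "ERROR":
            code = int(fields[1])
            message = fields[2] if len(fields) > 2 else ""
            raise NotFoundError(code, message) if code == 404 else RemoteError(code, message)
        raise ConnectionError(f"malformed status line {status!r}")

    @staticmethod
    def _filter_params(strand: str, minweight: Optional[float], endedness: str) -> Dict[str, object]:
        return {
            "strand": strand if strand != "both" else None,
            "minweight": minweight,
            "endedness": endedness if endedness != SINGLE else None,
        }

    # -- the interface -------------------------------------------------

    def store_single(self, align: str, chrom: int, hits: List[SingleHit]) -> None:
        lines = [f"{h.pos}\t{h.strand}\t{h.length}\t{_fmt_weight(h.weight)}" for h in hits]
        self._request("STORE", {"align": align, "chrom": chrom, "count": len(lines)}, lines)

    def store_paired(self, align: str, pairs: List[PairedHit]) -> None:
        lines = [
            f"{p.chrom}\t{p.pos}\t{p.strand}\t{p.length}\t{_fmt_weight(p.weight)}"
            f"\t{p.matechrom}\t{p.matepos}\t{p.matestrand}\t{p.matelength}"
            for p in pairs
        ]
        self._request("STOREPAIRED", {"align": align, "count": len(lines)}, lines)

    def delete(self, align: str, chrom: Optional[int] = None, endedness: str = "both") -> None:
        self._request("DELETE", {"align": align, "chrom": chrom, "endedness": endedness})

    def chroms(self, align: str) -> Dict[int, Dict[str, int]]:
        payload = self._request("CHROMS", {"align": align})
        out: Dict[int, Dict[str, int]] = {}
        for line in payload:
            c, s, pl, pr = line.split("\t")
            out[int(c)] = {SINGLE: int(s), PAIRED_LEFT: int(pl), PAIRED_RIGHT: int(pr)}
        return out

    def count(self, align: str, chrom: Optional[int] = None,
              start: Optional[int] = None, end: Optional[int] = None,
              strand: str = "both", minweight: Optional[float] = None,
              endedness: str = SINGLE) -> int:
        params: Dict[str, object] = {"align": align, "chrom": chrom, "start": start, "end": end}
        params.update(self._filter_params(strand, minweight, endedness))
        return int(self._request("COUNT", params)[0])

    def weight_sum(self, align: str, chrom: Optional[int] = None,
                   start: Optional[int] = None, end: Optional[int] = None,
                   strand: str = "both", minweight: Optional[float] = None,
                   endedness: str = SINGLE) -> float:
        params: Dict[str, object] = {"align": align, "chrom": chrom, "start": start, "end": end}
        params.update(self._filter_params(strand, minweight, endedness))
        return float(self._request("WEIGHTSUM", params)[0])

    def get_hits(self, align: str, chrom: int, start: int, end: int,
                 strand: str = "both", minweight: Optional[float] = None,
                 endedness: str = SINGLE, projection: str = "full"
                 ) -> Union[List[SingleHit], List[PairedHit], List[int], List[float]]:
        params: Dict[str, object] = {
            "align": align, "chrom": chrom, "start": start, "end": end,
            "projection": projection if projection != "full" else None,
        }
        params.update(self._filter_params(strand, minweight, endedness))
        payload = self._request("GETHITS", params)
        if projection == "positions":
            return [int(x) for x in payload]
        if projection == "weights":
            return [float(x) for x in payload]
        if endedness == SINGLE:
            out = []
            for line in payload:
                p, s, ln, w = line.split("\t")
                out.append(SingleHit(chrom=chrom, pos=int(p), strand=s,
                                     length=int(ln), weight=float(w)))
            return out
        pairs = []
        for line in payload:
            p, s, ln, w, mc, mp, ms, mln = line.split("\t")
            pairs.append(PairedHit(
                chrom=chrom, pos=int(p), strand=s, length=int(ln), weight=float(w),
                matechrom=int(mc), matepos=int(mp), matestrand=ms, matelength=int(mln),
            ))
        return pairs

    def histogram(self, align: str, chrom: int, start: int, end: int, binwidth: int,
                  mode: str = "count", strand: str = "both",
                  minweight: Optional[float] = None, endedness: str = SINGLE) -> Histogram:
        params: Dict[str, object] = {
            "align": align, "chrom": chrom, "start": start, "end": end,
            "binwidth": binwidth, "mode": mode if mode != "count" else None,
        }
        params.update(self._filter_params(strand, minweight, endedness))
        payload = self._request("HISTOGRAM", params)
        bins: Dict[int, float] = {}
        for line in payload:
            b, v = line.split("\t")
            bins[int(b)] = int(v) if mode == "count" else float(v)
        return Histogram(region=Region(chrom, start, end), binwidth=binwidth,
                         mode=mode, bins=bins)

    def shutdown(self) -> None:
        self._request("SHUTDOWN", {})

    def bye(self) -> None:
        self._request("BYE", {})
        self.close()
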