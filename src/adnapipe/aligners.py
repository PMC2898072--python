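"""Semi-global re-alignment and exact three-way alignment.

Two alignment flavours live here:

* :func:`semiglobal_align` -- global with respect to the read, local with
  respect to a genomic window (free end gaps on the window only), with
  affine gap costs.  Used to extend a seeded local hit to the full read.
* :func:`threeway_align` / :func:`threeway_align_dijkstra` -- optimal
  sum-of-pairs alignment of an ancient read with two reference segments
  over the full 3D lattice.  The Dijkstra variant traverses the same
  lattice best-first (costs made non-negative by a per-column shift of
  ``match`` per consumed character) and returns identical scores at a
  fraction of the cost for similar sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ParameterError, SizeError
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .seq import GAP_CODE, decode, encode


@dataclass
class SemiGlobalAlignment:
    """A read aligned globally against a local target window."""

    query_id: str
    target_name: str
    target_start: int  # genome coordinates of the aligned window part
    target_end: int
    strand: str
    query_row: str
    target_row: str
    score: int

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.target_row):
            raise ParameterError("alignment rows must have equal length")

    @property
    def query_length(self) -> int:
        return sum(1 for c in self.query_row if c != "-")


@dataclass
class ThreeWayAlignment:
    """Gapped ancient/species-A/species-B rows of equal length."""

    rows: tuple[str, str, str]
    score: int

    def __post_init__(self) -> None:
        n, h, c = self.rows
        if not (len(n) == len(h) == len(c)):
            raise ParameterError("three-way rows must have equal length")
        if any(a == "-" and b == "-" and d == "-" for a, b, d in zip(n, h, c)):
            raise ParameterError("no column may be gap in all three rows")


def _traceback_pair(q, t, end_i, end_j, end_state, ptr_m, ptr_gq, ptr_gt):
    """Walk pairwise DP pointers back to the origin; returns gapped rows
    (as code lists, reversed) and the start cell."""
    rq: list[int] = []
    rt: list[int] = []
    i, j, state = end_i, end_j, end_state
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                break  # semiglobal start row
            nxt = ptr_m[i, j]
            rq.append(q[i - 1])
            rt.append(t[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            nxt = ptr_gq[i, j]
            rq.append(GAP_CODE)
            rt.append(t[j - 1])
            j -= 1
        else:
            nxt = ptr_gt[i, j]
            rq.append(q[i - 1])
            rt.append(GAP_CODE)
            i -= 1
        state = nxt
    return rq, rt, i, j


def semiglobal_align(
    read: str,
    window: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "",
    target_name: str = "",
    window_offset: int = 0,
    strand: str = "+",
) -> SemiGlobalAlignment:
    """Optimally align the full read inside a target window.

    ``window_offset`` is added to the reported target coordinates so hits
    can be expressed in genome coordinates.
    """
    if len(window) == 0:
        raise ParameterError("empty target window")
    if len(read) == 0:
        raise ParameterError("empty read")
    q = encode(read)
    t = encode(window)
    score, end_j, end_state, pm, pgq, pgt = _kernels.semiglobal(
        q, t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    rq, rt, _i, start_j = _traceback_pair(q, t, q.size, end_j, end_state, pm, pgq, pgt)
    q_row = decode(np.array(rq[::-1], dtype=np.uint8))
    t_row = decode(np.array(rt[::-1], dtype=np.uint8))
    return SemiGlobalAlignment(
        query_id=query_id,
        target_name=target_name,
        target_start=window_offset + start_j,
        target_end=window_offset + end_j,
        strand=strand,
        query_row=q_row,
        target_row=t_row,
        score=int(score),
    )


def positive_score_filter(alignment: SemiGlobalAlignment) -> bool:
    """True iff the semi-global score is strictly positive."""
    return alignment.score > 0


def local_align_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Exhaustive Smith-Waterman local alignment score (affine gaps)."""
    return int(
        _kernels.smith_waterman(
            encode(a),
            encode(b),
            scheme.match,
            scheme.mismatch,
            scheme.gap_open,
            scheme.gap_extend,
        )
    )


def _rows_from_masks(seqs: tuple[np.ndarray, np.ndarray, np.ndarray], masks) -> tuple[str, str, str]:
    idx = [0, 0, 0]
    rows: list[list[int]] = [[], [], []]
    for mask in masks:
        for s in range(3):
            if (mask >> s) & 1:
                rows[s].append(seqs[s][idx[s]])
                idx[s] += 1
            else:
                rows[s].append(GAP_CODE)
    return tuple(decode(np.array(r, dtype=np.uint8)) for r in rows)  # type: ignore[return-value]


DEFAULT_FULL_CAP = 3_000_000  # lattice cells (product of lengths + 1)
DEFAULT_DIJKSTRA_CAP = 200_000_000


def threeway_align(
    seq_n: str,
    seq_h: str,
    seq_c: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cap: int = DEFAULT_FULL_CAP,
) -> ThreeWayAlignment:
    """Optimal three-way alignment by exhaustive 3D dynamic programming."""
    if not (seq_n and seq_h and seq_c):
        raise ParameterError("all three sequences must be non-empty")
    s1, s2, s3 = encode(seq_n), encode(seq_h), encode(seq_c)
    cells = (s1.size + 1) * (s2.size + 1) * (s3.size + 1)
    if cells > cap:
        raise SizeError(
            f"3DP lattice has {cells} cells (cap {cap}); "
            "use threeway_align_dijkstra for long similar sequences"
        )
    score, masks, count = _kernels.threeway_full(
        s1, s2, s3, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    rows = _rows_from_masks((s1, s2, s3), masks[:count])
    return ThreeWayAlignment(rows=rows, score=int(score))


class _DijkstraWorkspace:
    """Reusable buffers for the Dijkstra traversal (reset between calls)."""

    def __init__(self) -> None:
        self.dist = np.full(0, _kernels.INF32, dtype=np.int32)
        self.pred = np.zeros(0, dtype=np.int8)
        self.touched = np.zeros(0, dtype=np.int64)
        self.heap = np.zeros(1 << 20, dtype=np.int64)
        self.masks = np.zeros(0, dtype=np.int8)

    def ensure(self, total_nodes: int, max_cols: int) -> None:
        if self.dist.size < total_nodes:
            self.dist = np.full(total_nodes, _kernels.INF32, dtype=np.int32)
            self.pred = np.zeros(total_nodes, dtype=np.int8)
            self.touched = np.zeros(total_nodes, dtype=np.int64)
        if self.masks.size < max_cols:
            self.masks = np.zeros(max_cols, dtype=np.int8)


_WORKSPACE = _DijkstraWorkspace()


def threeway_align_dijkstra(
    seq_n: str,
    seq_h: str,
    seq_c: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cap: int = DEFAULT_DIJKSTRA_CAP,
) -> ThreeWayAlignment:
    """Three-way alignment via best-first lattice traversal.

    Produces the same score as :func:`threeway_align` on every input but
    only settles lattice nodes whose cost is below the optimum, which for
    highly similar triples is a thin tube around the main diagonal.
    """
    if not (seq_n and seq_h and seq_c):
        raise ParameterError("all three sequences must be non-empty")
    s1, s2, s3 = encode(seq_n), encode(seq_h), encode(seq_c)
    total = (s1.size + 1) * (s2.size + 1) * (s3.size + 1) * 8
    if total > cap:
        raise SizeError(f"lattice has {total} nodes (cap {cap})")
    _WORKSPACE.ensure(total, s1.size + s2.size + s3.size)
    while True:
        score, count, status = _kernels.threeway_dijkstra(
            s1,
            s2,
            s3,
            scheme.match,
            scheme.mismatch,
            scheme.gap_open,
            scheme.gap_extend,
            _WORKSPACE.dist,
            _WORKSPACE.pred,
            _WORKSPACE.touched,
            _WORKSPACE.heap,
            _WORKSPACE.masks,
        )
        if status == 1:  # heap overflow: grow and retry
            _WORKSPACE.heap = np.zeros(_WORKSPACE.heap.size * 2, dtype=np.int64)
            continue
        if status == 2:  # workspace race; should not happen after ensure()
            raise SizeError("Dijkstra workspace too small")
        break
    rows = _rows_from_masks((s1, s2, s3), _WORKSPACE.masks[:count])
    return ThreeWayAlignment(rows=rows, score=int(score))
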