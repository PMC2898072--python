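"""Independent brute-force oracles used only by the test suite.

These are deliberately naive re-implementations (plain-Python full DP,
per-column enumeration) kept separate from the package code paths they
check.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def smith_waterman_py(a: str, b: str, match=1, mismatch=-3, go=-5, ge=-2) -> int:
    """Exhaustive local affine alignment score, plain Python."""
    na, nb = len(a), len(b)
    m = [[0.0] * (nb + 1) for _ in range(na + 1)]
    ga_ = [[NEG] * (nb + 1) for _ in range(na + 1)]
    gb_ = [[NEG] * (nb + 1) for _ in range(na + 1)]
    best = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            m[i][j] = max(0.0, max(m[i - 1][j - 1], ga_[i - 1][j - 1], gb_[i - 1][j - 1]) + s)
            ga_[i][j] = max(m[i][j - 1] + go + ge, ga_[i][j - 1] + ge, gb_[i][j - 1] + go + ge)
            gb_[i][j] = max(m[i - 1][j] + go + ge, ga_[i - 1][j] + go + ge, gb_[i - 1][j] + ge)
            best = max(best, m[i][j])
    return int(best)


def glocal_py(q: str, t: str, match=1, mismatch=-3, go=-5, ge=-2) -> int:
    """Global-in-query, free-target-end-gaps alignment score, plain Python."""
    nq, nt = len(q), len(t)
    m = [[NEG] * (nt + 1) for _ in range(nq + 1)]
    gq = [[NEG] * (nt + 1) for _ in range(nq + 1)]
    gt = [[NEG] * (nt + 1) for _ in range(nq + 1)]
    for j in range(nt + 1):
        m[0][j] = 0.0
    for i in range(1, nq + 1):
        gt[i][0] = go + i * ge
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            m[i][j] = max(m[i - 1][j - 1], gq[i - 1][j - 1], gt[i - 1][j - 1]) + s
            gq[i][j] = max(m[i][j - 1] + go + ge, gq[i][j - 1] + ge, gt[i][j - 1] + go + ge)
            gt[i][j] = max(m[i - 1][j] + go + ge, gq[i - 1][j] + go + ge, gt[i - 1][j] + ge)
    return int(max(max(m[nq][j], gt[nq][j]) for j in range(nt + 1)))


def threeway_py(s1: str, s2: str, s3: str, match=1, mismatch=-3, go=-5, ge=-2) -> int:
    """Optimal sum-of-pairs three-way score by memoized recursion.

    Column scoring: advancing pairs score match/mismatch; an advancing
    vs non-advancing pair is charged extend plus open when the gapped
    sequence advanced in the previous column; gap-vs-gap scores 0.
    """

    def pair(adv_x, adv_y, prev_x, prev_y, cx, cy):
        if adv_x and adv_y:
            return match if cx == cy else mismatch
        if adv_x:
            return ge + (go if prev_y else 0)
        if adv_y:
            return ge + (go if prev_x else 0)
        return 0

    @lru_cache(maxsize=None)
    def rec(i, j, k, pmask):
        if i == len(s1) and j == len(s2) and k == len(s3):
            return 0
        best = NEG
        for mask in range(1, 8):
            b0, b1, b2 = mask & 1, (mask >> 1) & 1, (mask >> 2) & 1
            ni, nj, nk = i + b0, j + b1, k + b2
            if ni > len(s1) or nj > len(s2) or nk > len(s3):
                continue
            c1 = s1[i] if b0 else ""
            c2 = s2[j] if b1 else ""
            c3 = s3[k] if b2 else ""
            col = (
                pair(b0, b1, pmask & 1, (pmask >> 1) & 1, c1, c2)
                + pair(b0, b2, pmask & 1, (pmask >> 2) & 1, c1, c3)
                + pair(b1, b2, (pmask >> 1) & 1, (pmask >> 2) & 1, c2, c3)
            )
            cand = col + rec(ni, nj, nk, mask)
            if cand > best:
                best = cand
        return best

    result = rec(0, 0, 0, 7)
    rec.cache_clear()
    return int(result)


def liftover_py(gapped_a: str, gapped_b: str, start: int, end: int):
    """Per-column image enumeration of an A interval in B (one block)."""
    a_pos = -1
    b_pos = -1
    images = []
    for ca, cb in zip(gapped_a, gapped_b):
        if ca != "-":
            a_pos += 1
        if cb != "-":
            b_pos += 1
        if ca != "-" and cb != "-" and start <= a_pos < end:
            images.append(b_pos)
    if not images:
        return None
    return min(images), max(images) + 1


def identity_py(short: str, long_: str) -> float:
    """Best global identity of the shorter read against any slice of the
    longer, by edit-path enumeration via simple DP (match-count based).

    Used as an approximate cross-check only for constructed cases where
    the intended alignment is unambiguous (no indels)."""
    best = 0
    for off in range(0, len(long_) - len(short) + 1):
        m = sum(1 for a, b in zip(short, long_[off:]) if a == b)
        best = max(best, m)
    return best / len(short)
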