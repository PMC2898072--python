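"""Numba dynamic-programming kernels.

All kernels operate on uint8 code arrays (A=0..T=3) and integer scores.
Affine gaps cost ``gap_open + k * gap_extend`` for a gap of k columns.
Matrix states follow the usual M / gap-in-query / gap-in-target split;
three-way kernels use a per-column advance mask (bit0 = sequence 1,
bit1 = sequence 2, bit2 = sequence 3) with the previous column's mask
kept in the DP state so gap openings can be charged per sequence pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**28)
INF32 = 2**31 - 1

# mask preference order used for deterministic tie-breaking: all-advance
# first, then a single gap in sequence 1, 2, 3, then double gaps
PREF_MASKS = np.array([7, 6, 5, 3, 4, 2, 1], dtype=np.int8)


@njit(cache=True)
def ungapped_extend(q, t, qpos, tpos, k, match, mismatch, xdrop):
    """Two-directional ungapped X-drop extension of an exact k-mer seed.

    Returns (q_lo, q_hi, score); target coordinates follow from the
    seed diagonal (t_lo = tpos - (qpos - q_lo)).
    """
    score = k * match
    best = score
    q_hi = qpos + k
    i = qpos + k
    j = tpos + k
    while i < q.size and j < t.size:
        score += match if q[i] == t[j] else mismatch
        i += 1
        j += 1
        if score > best:
            best = score
            q_hi = i
        elif best - score > xdrop:
            break
    cur = best
    q_lo = qpos
    i = qpos - 1
    j = tpos - 1
    while i >= 0 and j >= 0:
        cur += match if q[i] == t[j] else mismatch
        if cur > best:
            best = cur
            q_lo = i
        elif best - cur > xdrop:
            break
        i -= 1
        j -= 1
    return q_lo, q_hi, best


@njit(cache=True)
def gapped_extend(q, t, match, mismatch, go, ge, xdrop):
    """Affine gapped X-drop extension anchored at (0, 0).

    Aligns prefixes of ``q`` and ``t`` (the extension direction is the
    caller's concern: pass reversed slices for leftward extension).
    Cells falling more than ``xdrop`` below the running best are pruned.

    Returns (best_score, best_i, best_j, ptr_m, ptr_gq, ptr_gt) where the
    pointer codes are 0=M, 1=Gq (gap in q, consumes t), 2=Gt (gap in t,
    consumes q).
    """
    nq, nt = q.size, t.size
    m = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    gq = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    gt = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    ptr_m = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    ptr_gq = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    ptr_gt = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    m[0, 0] = 0
    for j in range(1, nt + 1):
        gq[0, j] = go + j * ge
        ptr_gq[0, j] = 1 if j > 1 else 0
    for i in range(1, nq + 1):
        gt[i, 0] = go + i * ge
        ptr_gt[i, 0] = 2 if i > 1 else 0
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            sub = match if q[i - 1] == t[j - 1] else mismatch
            # match state
            v0 = m[i - 1, j - 1]
            v1 = gq[i - 1, j - 1]
            v2 = gt[i - 1, j - 1]
            vm = v0
            pm = 0
            if v1 > vm:
                vm = v1
                pm = 1
            if v2 > vm:
                vm = v2
                pm = 2
            if vm > NEG // 2:
                vm += sub
            m[i, j] = vm
            ptr_m[i, j] = pm
            # gap in q (consume t[j-1])
            a0 = m[i, j - 1] + go + ge
            a1 = gq[i, j - 1] + ge
            a2 = gt[i, j - 1] + go + ge
            vg = a0
            pg = 0
            if a1 > vg:
                vg = a1
                pg = 1
            if a2 > vg:
                vg = a2
                pg = 2
            gq[i, j] = vg
            ptr_gq[i, j] = pg
            # gap in t (consume q[i-1])
            b0 = m[i - 1, j] + go + ge
            b1 = gq[i - 1, j] + go + ge
            b2 = gt[i - 1, j] + ge
            vt = b0
            pt = 0
            if b1 > vt:
                vt = b1
                pt = 1
            if b2 > vt:
                vt = b2
                pt = 2
            gt[i, j] = vt
            ptr_gt[i, j] = pt
            if m[i, j] > best:
                best = m[i, j]
                best_i = i
                best_j = j
            # X-drop pruning
            if best - m[i, j] > xdrop:
                m[i, j] = NEG
            if best - gq[i, j] > xdrop:
                gq[i, j] = NEG
            if best - gt[i, j] > xdrop:
                gt[i, j] = NEG
    return best, best_i, best_j, ptr_m, ptr_gq, ptr_gt


@njit(cache=True)
def semiglobal(q, t, match, mismatch, go, ge):
    """Glocal alignment: global in ``q``, free end gaps in ``t``.

    Every query base is consumed; leading/trailing target bases outside
    the alignment are free.  Returns (score, end_i=nq, end_j, end_state,
    ptr_m, ptr_gq, ptr_gt).
    """
    nq, nt = q.size, t.size
    m = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    gq = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    gt = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    ptr_m = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    ptr_gq = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    ptr_gt = np.zeros((nq + 1, nt + 1), dtype=np.int8)
    for j in range(nt + 1):
        m[0, j] = 0  # alignment may start at any target offset for free
    for i in range(1, nq + 1):
        gt[i, 0] = go + i * ge
        ptr_gt[i, 0] = 2 if i > 1 else 0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            sub = match if q[i - 1] == t[j - 1] else mismatch
            v0 = m[i - 1, j - 1]
            v1 = gq[i - 1, j - 1]
            v2 = gt[i - 1, j - 1]
            vm = v0
            pm = 0
            if v1 > vm:
                vm = v1
                pm = 1
            if v2 > vm:
                vm = v2
                pm = 2
            if vm > NEG // 2:
                vm += sub
            m[i, j] = vm
            ptr_m[i, j] = pm
            a0 = m[i, j - 1] + go + ge
            a1 = gq[i, j - 1] + ge
            a2 = gt[i, j - 1] + go + ge
            vg = a0
            pg = 0
            if a1 > vg:
                vg = a1
                pg = 1
            if a2 > vg:
                vg = a2
                pg = 2
            gq[i, j] = vg
            ptr_gq[i, j] = pg
            b0 = m[i - 1, j] + go + ge
            b1 = gq[i - 1, j] + go + ge
            b2 = gt[i - 1, j] + ge
            vt = b0
            pt = 0
            if b1 > vt:
                vt = b1
                pt = 1
            if b2 > vt:
                vt = b2
                pt = 2
            gt[i, j] = vt
            ptr_gt[i, j] = pt
    best = NEG
    end_j = 0
    end_state = 0
    for j in range(nt + 1):
        if m[nq, j] > best:
            best = m[nq, j]
            end_j = j
            end_state = 0
        if gt[nq, j] > best:
            best = gt[nq, j]
            end_j = j
            end_state = 2
    return best, end_j, end_state, ptr_m, ptr_gq, ptr_gt


@njit(cache=True)
def smith_waterman(q, t, match, mismatch, go, ge):
    """Exhaustive local affine alignment; returns the optimal score."""
    nq, nt = q.size, t.size
    m_prev = np.zeros(nt + 1, dtype=np.int32)
    gq_prev = np.full(nt + 1, NEG, dtype=np.int32)
    gt_prev = np.full(nt + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, nq + 1):
        m_cur = np.zeros(nt + 1, dtype=np.int32)
        gq_cur = np.full(nt + 1, NEG, dtype=np.int32)
        gt_cur = np.full(nt + 1, NEG, dtype=np.int32)
        m_cur[0] = 0
        for j in range(1, nt + 1):
            sub = match if q[i - 1] == t[j - 1] else mismatch
            vm = m_prev[j - 1]
            if gq_prev[j - 1] > vm:
                vm = gq_prev[j - 1]
            if gt_prev[j - 1] > vm:
                vm = gt_prev[j - 1]
            vm = vm + sub
            if vm < 0:
                vm = 0
            m_cur[j] = vm
            vg = m_cur[j - 1] + go + ge
            if gq_cur[j - 1] + ge > vg:
                vg = gq_cur[j - 1] + ge
            if gt_cur[j - 1] + go + ge > vg:
                vg = gt_cur[j - 1] + go + ge
            gq_cur[j] = vg
            vt = m_prev[j] + go + ge
            if gq_prev[j] + go + ge > vt:
                vt = gq_prev[j] + go + ge
            if gt_prev[j] + ge > vt:
                vt = gt_prev[j] + ge
            gt_cur[j] = vt
            if m_cur[j] > best:
                best = m_cur[j]
        m_prev, gq_prev, gt_prev = m_cur, gq_cur, gt_cur
    return best


@njit(cache=True, inline="always")
def _pair_col_score(adv_x, adv_y, prev_x, prev_y, cx, cy, match, mismatch, go, ge):
    if adv_x == 1 and adv_y == 1:
        return match if cx == cy else mismatch
    if adv_x == 1:
        return ge + (go if prev_y == 1 else 0)
    if adv_y == 1:
        return ge + (go if prev_x == 1 else 0)
    return 0


@njit(cache=True, inline="always")
def _col_score(mask, pmask, c1, c2, c3, match, mismatch, go, ge):
    b0 = (mask >> 0) & 1
    b1 = (mask >> 1) & 1
    b2 = (mask >> 2) & 1
    p0 = (pmask >> 0) & 1
    p1 = (pmask >> 1) & 1
    p2 = (pmask >> 2) & 1
    s = _pair_col_score(b0, b1, p0, p1, c1, c2, match, mismatch, go, ge)
    s += _pair_col_score(b0, b2, p0, p2, c1, c3, match, mismatch, go, ge)
    s += _pair_col_score(b1, b2, p1, p2, c2, c3, match, mismatch, go, ge)
    return s


@njit(cache=True)
def threeway_full(s1, s2, s3, match, mismatch, go, ge):
    """Exhaustive 3D dynamic programming over a sequence triple.

    Sum-of-pairs scoring over the three pairwise projections; gap-vs-gap
    in a pair scores 0.  Returns (score, masks, n_cols) with ``masks``
    holding the per-column advance masks of the traceback in order.
    """
    n1, n2, n3 = s1.size, s2.size, s3.size
    d = np.full((n1 + 1, n2 + 1, n3 + 1, 8), NEG, dtype=np.int32)
    p = np.full((n1 + 1, n2 + 1, n3 + 1, 8), -1, dtype=np.int8)
    d[0, 0, 0, 7] = 0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                for mi in range(7):
                    mask = PREF_MASKS[mi]
                    b0 = (mask >> 0) & 1
                    b1 = (mask >> 1) & 1
                    b2 = (mask >> 2) & 1
                    if i < b0 or j < b1 or k < b2:
                        continue
                    c1 = s1[i - 1] if b0 == 1 else np.uint8(0)
                    c2 = s2[j - 1] if b1 == 1 else np.uint8(0)
                    c3 = s3[k - 1] if b2 == 1 else np.uint8(0)
                    best = NEG
                    best_pm = -1
                    for pmi in range(7):
                        pm = PREF_MASKS[pmi]
                        base = d[i - b0, j - b1, k - b2, pm]
                        if base <= NEG // 2:
                            continue
                        sc = base + _col_score(
                            mask, pm, c1, c2, c3, match, mismatch, go, ge
                        )
                        if sc > best:
                            best = sc
                            best_pm = pm
                    if best > NEG // 2:
                        d[i, j, k, mask] = best
                        p[i, j, k, mask] = best_pm
    best = NEG
    best_mask = 7
    for mi in range(7):
        mask = PREF_MASKS[mi]
        if d[n1, n2, n3, mask] > best:
            best = d[n1, n2, n3, mask]
            best_mask = mask
    # traceback
    masks = np.zeros(n1 + n2 + n3, dtype=np.int8)
    count = 0
    i, j, k = n1, n2, n3
    cm = best_mask
    while i > 0 or j > 0 or k > 0:
        masks[count] = cm
        count += 1
        pm = p[i, j, k, cm]
        i -= (cm >> 0) & 1
        j -= (cm >> 1) & 1
        k -= (cm >> 2) & 1
        cm = pm
    # reverse in place
    for a in range(count // 2):
        tmp = masks[a]
        masks[a] = masks[count - 1 - a]
        masks[count - 1 - a] = tmp
    return best, masks, count


@njit(cache=True, inline="always")
def _heap_push(heap, hsize, key):
    heap[hsize] = key
    c = hsize
    while c > 0:
        par = (c - 1) >> 1
        if heap[par] > heap[c]:
            heap[par], heap[c] = heap[c], heap[par]
            c = par
        else:
            break
    return hsize + 1


@njit(cache=True, inline="always")
def _heap_pop(heap, hsize):
    top = heap[0]
    hsize -= 1
    heap[0] = heap[hsize]
    c = 0
    while True:
        l = 2 * c + 1
        r = l + 1
        small = c
        if l < hsize and heap[l] < heap[small]:
            small = l
        if r < hsize and heap[r] < heap[small]:
            small = r
        if small == c:
            break
        heap[c], heap[small] = heap[small], heap[c]
        c = small
    return top, hsize


@njit(cache=True)
def threeway_dijkstra(
    s1, s2, s3, match, mismatch, go, ge, dist, pred, touched, heap, masks
):
    """Best-first (Dijkstra) traversal of the 3DP lattice.

    Maximization is converted to minimization by charging each column
    ``match * (#sequences advanced) - column_score``, which is >= 0 for
    every column type, so Dijkstra applies and the first settled final
    node is optimal.  Scores equal :func:`threeway_full` exactly.

    ``dist`` (int32, >= (n1+1)(n2+1)(n3+1)*8, pre-filled with INF32),
    ``pred`` (int8, same size), ``touched`` (int64 scratch), ``heap``
    (int64 scratch) and ``masks`` (int8, >= n1+n2+n3) are caller-provided
    workspaces; ``dist`` entries used are restored to INF32 on exit.

    Returns (score, n_cols, status); status 1 means heap overflow (the
    caller should retry with a larger heap), 2 means workspace too small.
    """
    n1, n2, n3 = s1.size, s2.size, s3.size
    total = (n1 + 1) * (n2 + 1) * (n3 + 1) * 8
    if total > dist.size or total > pred.size or n1 + n2 + n3 > masks.size:
        return 0, 0, 2
    sj = (n3 + 1) * 8
    si = (n2 + 1) * sj
    start = (0 * si + 0 * sj + 0 * 8) + 7
    ntouch = 0
    hsize = 0
    dist[start] = 0
    pred[start] = -1
    touched[ntouch] = start
    ntouch += 1
    hsize = _heap_push(heap, hsize, (np.int64(0) << np.int64(32)) | np.int64(start))
    final_cost = -1
    final_mask = -1
    while hsize > 0:
        key, hsize = _heap_pop(heap, hsize)
        node = key & np.int64(0xFFFFFFFF)
        cost = key >> np.int64(32)
        if cost != dist[node]:
            continue
        m = node & 7
        r = node >> 3
        k = r % (n3 + 1)
        r //= n3 + 1
        j = r % (n2 + 1)
        i = r // (n2 + 1)
        if i == n1 and j == n2 and k == n3:
            final_cost = cost
            final_mask = m
            break
        for nmi in range(7):
            nm = PREF_MASKS[nmi]
            b0 = (nm >> 0) & 1
            b1 = (nm >> 1) & 1
            b2 = (nm >> 2) & 1
            ni = i + b0
            nj = j + b1
            nk = k + b2
            if ni > n1 or nj > n2 or nk > n3:
                continue
            c1 = s1[ni - 1] if b0 == 1 else np.uint8(0)
            c2 = s2[nj - 1] if b1 == 1 else np.uint8(0)
            c3 = s3[nk - 1] if b2 == 1 else np.uint8(0)
            sc = _col_score(nm, m, c1, c2, c3, match, mismatch, go, ge)
            edge = match * (b0 + b1 + b2) - sc
            nd = cost + edge
            nnode = ni * si + nj * sj + nk * 8 + nm
            if nd < dist[nnode]:
                if dist[nnode] == INF32:
                    touched[ntouch] = nnode
                    ntouch += 1
                dist[nnode] = np.int32(nd)
                pred[nnode] = np.int8(m)
                if hsize >= heap.size:
                    for a in range(ntouch):
                        dist[touched[a]] = INF32
                    return 0, 0, 1
                hsize = _heap_push(
                    heap, hsize, (np.int64(nd) << np.int64(32)) | np.int64(nnode)
                )
    # traceback
    count = 0
    if final_cost >= 0:
        i, j, k = n1, n2, n3
        cm = final_mask
        while i > 0 or j > 0 or k > 0:
            masks[count] = cm
            count += 1
            pm = pred[i * si + j * sj + k * 8 + cm]
            i -= (cm >> 0) & 1
            j -= (cm >> 1) & 1
            k -= (cm >> 2) & 1
            cm = pm
        for a in range(count // 2):
            tmp = masks[a]
            masks[a] = masks[count - 1 - a]
            masks[count - 1 - a] = tmp
    score = match * (n1 + n2 + n3) - final_cost
    for a in range(ntouch):
        dist[touched[a]] = INF32
    return score, count, 0
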