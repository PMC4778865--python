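"""Numba kernels for the p-median heuristic.

The local search is a vertex-substitution (swap) search with the classic
fast-interchange bookkeeping: for every demand point we cache the distance to
its nearest and second-nearest open facility, and we maintain

    gain[c]     = sum_m max(d1[m] - D[m, c], 0)
    extraT[f, c] = sum_{m: nearest(m) = f} [ max(d1-Dc, 0) + min(d2, Dc) - d1 ]

so that the exact objective change of swapping facility ``f`` out for
candidate ``c`` is ``delta(c, f) = extraT[f, c] - gain[c]``.  After a swap only
demand points whose two nearest facilities changed touch these tables, which
makes a swap O(changed * n) instead of O(m * n).  The same tables drive
path-relinking walks between elite solutions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True)
def assign_all(D, sel, d1, d2, a1, a2):
    """Nearest / second-nearest open facility for every demand point.

    Ties go to the lowest site index (``sel`` must be sorted ascending).
    """
    m = D.shape[0]
    p = sel.shape[0]
    for mm in range(m):
        b1 = INF
        b2 = INF
        i1 = -1
        i2 = -1
        for t in range(p):
            f = sel[t]
            v = D[mm, f]
            if v < b1:
                b2 = b1
                i2 = i1
                b1 = v
                i1 = f
            elif v < b2:
                b2 = v
                i2 = f
        d1[mm] = b1
        d2[mm] = b2
        a1[mm] = i1
        a2[mm] = i2


@njit(cache=True)
def build_gain_extra(D, d1, d2, a1, gain, extraT):
    m, n = D.shape
    for c in range(n):
        gain[c] = 0.0
    for f in range(n):
        for c in range(n):
            extraT[f, c] = 0.0
    for mm in range(m):
        dd1 = d1[mm]
        dd2 = d2[mm]
        f = a1[mm]
        for c in range(n):
            Dc = D[mm, c]
            g = dd1 - Dc
            if g < 0.0:
                g = 0.0
            gain[c] += g
            second = dd2 if dd2 < Dc else Dc
            extraT[f, c] += g + second - dd1


@njit(cache=True)
def best_swap(gain, extraT, sel, insol):
    """Most-improving (candidate, facility) swap; ties -> lowest indices."""
    n = gain.shape[0]
    p = sel.shape[0]
    best = INF
    bc = -1
    bf = -1
    for t in range(p):
        f = sel[t]
        for c in range(n):
            if insol[c]:
                continue
            delta = extraT[f, c] - gain[c]
            if delta < best or (delta == best and
                                (c < bc or (c == bc and f < bf))):
                best = delta
                bc = c
                bf = f
    return bc, bf, best


@njit(cache=True)
def apply_swap(D, sel, insol, d1, d2, a1, a2, gain, extraT, c_in, f_out):
    """Swap f_out -> c_in, incrementally repairing assignments and tables."""
    m, n = D.shape
    p = sel.shape[0]
    for t in range(p):
        if sel[t] == f_out:
            sel[t] = c_in
            break
    sel.sort()
    insol[f_out] = False
    insol[c_in] = True
    for mm in range(m):
        old1 = d1[mm]
        old2 = d2[mm]
        oa1 = a1[mm]
        oa2 = a2[mm]
        Dc = D[mm, c_in]
        if oa1 == f_out or oa2 == f_out:
            # lost one of the two nearest: rescan over the new solution
            b1 = INF
            b2 = INF
            i1 = -1
            i2 = -1
            for t in range(p):
                f = sel[t]
                v = D[mm, f]
                if v < b1:
                    b2 = b1
                    i2 = i1
                    b1 = v
                    i1 = f
                elif v < b2:
                    b2 = v
                    i2 = f
            n1, n2, na1, na2 = b1, b2, i1, i2
        elif Dc < old2:
            if Dc < old1:
                n1, na1, n2, na2 = Dc, c_in, old1, oa1
            else:
                n1, na1, n2, na2 = old1, oa1, Dc, c_in
        else:
            continue
        if n1 != old1 or n2 != old2 or na1 != oa1:
            for c in range(n):
                Dcc = D[mm, c]
                g = old1 - Dcc
                if g < 0.0:
                    g = 0.0
                second = old2 if old2 < Dcc else Dcc
                gain[c] -= g
                extraT[oa1, c] -= g + second - old1
                g = n1 - Dcc
                if g < 0.0:
                    g = 0.0
                second = n2 if n2 < Dcc else Dcc
                gain[c] += g
                extraT[na1, c] += g + second - n1
        d1[mm] = n1
        d2[mm] = n2
        a1[mm] = na1
        a2[mm] = na2


@njit(cache=True)
def local_search(D, sel, insol, d1, d2, a1, a2, gain, extraT, eps, max_swaps):
    """Repeat best-improving swaps until a local optimum; returns swap count.

    Tables are rebuilt from scratch every 64 swaps to bound floating-point
    drift from the incremental updates.
    """
    swaps = 0
    while swaps < max_swaps:
        bc, bf, delta = best_swap(gain, extraT, sel, insol)
        if bc < 0 or delta >= -eps:
            break
        apply_swap(D, sel, insol, d1, d2, a1, a2, gain, extraT, bc, bf)
        swaps += 1
        if swaps % 64 == 0:
            assign_all(D, sel, d1, d2, a1, a2)
            build_gain_extra(D, d1, d2, a1, gain, extraT)
    return swaps


@njit(cache=True)
def path_relink(D, start_sel, guide_sel, insol, d1, d2, a1, a2, gain, extraT):
    """Walk from start_sel toward guide_sel, one best swap at a time.

    Every step swaps an element of ``cur \\ guide`` for one of
    ``guide \\ cur`` (the least-cost such swap, even if worsening) so the walk
    terminates after |difference| steps.  Returns the best solution visited
    and its objective.
    """
    m, n = D.shape
    p = start_sel.shape[0]
    sel = start_sel.copy()
    for c in range(n):
        insol[c] = False
    for t in range(p):
        insol[sel[t]] = True
    in_guide = np.zeros(n, np.bool_)
    for t in range(p):
        in_guide[guide_sel[t]] = True
    assign_all(D, sel, d1, d2, a1, a2)
    build_gain_extra(D, d1, d2, a1, gain, extraT)
    obj = 0.0
    for mm in range(m):
        obj += d1[mm]
    best_obj = obj
    best_sel = sel.copy()
    while True:
        bc = -1
        bf = -1
        bdelta = INF
        for t in range(p):
            f = sel[t]
            if in_guide[f]:
                continue
            for c in range(n):
                if insol[c] or not in_guide[c]:
                    continue
                delta = extraT[f, c] - gain[c]
                if delta < bdelta or (delta == bdelta and
                                      (c < bc or (c == bc and f < bf))):
                    bdelta = delta
                    bc = c
                    bf = f
        if bc < 0:
            break
        apply_swap(D, sel, insol, d1, d2, a1, a2, gain, extraT, bc, bf)
        obj += bdelta
        if obj < best_obj:
            best_obj = obj
            best_sel = sel.copy()
    return best_sel, best_obj


@njit(cache=True)
def greedy_construct(DT, p, cand_rows):
    """Greedy construction choosing, at each step, the best candidate of a row.

    ``DT`` is the transposed distance matrix (site x demand point), so each
    candidate evaluation streams one contiguous row.  ``cand_rows`` has one
    row of candidate site indices per step (already random for the sampled-
    greedy starts, or 0..n-1 for the deterministic full greedy).  Already-
    selected candidates are skipped; ties -> lowest index.
    """
    n, m = DT.shape
    d1 = np.full(m, INF)
    insol = np.zeros(n, np.bool_)
    sel = np.empty(p, np.int64)
    for step in range(p):
        best = INF
        bcand = -1
        for t in range(cand_rows.shape[1]):
            c = cand_rows[step, t]
            if insol[c]:
                continue
            s = 0.0
            for mm in range(m):
                v = DT[c, mm]
                s += v if v < d1[mm] else d1[mm]
            if s < best or (s == best and (bcand < 0 or c < bcand)):
                best = s
                bcand = c
        if bcand < 0:
            for c in range(n):
                if not insol[c]:
                    bcand = c
                    break
        insol[bcand] = True
        sel[step] = bcand
        for mm in range(m):
            v = DT[bcand, mm]
            if v < d1[mm]:
                d1[mm] = v
    sel.sort()
    return sel
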