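"""Numba kernels for the multidimensional-scaling inner loop.

One majorization (SMACOF-style) kernel serves both NMDS and HMDS: each
iteration fits monotone disparities to the current configuration distances
(Kruskal's primary approach to ties), optionally blends in a metric target
``s * delta`` for pairs below the hybrid threshold, and applies a weighted
Guttman transform.  NMDS is the ``metric_weight = 0`` special case, so the
two methods share one code path exactly.

The kernel works entirely in the dissimilarity-sorted ("ordered") domain:
position t carries the packed site pair ``ijbuf[t]`` and its current
configuration distance ``ybuf[t]``.  Re-sorting tie groups by distance moves
both arrays together, so every pass is sequential and the only random access
is into the (cache-resident) coordinate array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pava", "smacof_start", "condensed_distances", "pack_pairs"]

_LOW32 = np.int64((1 << 32) - 1)


@njit(cache=True)
def _pava_work(y, level, weight, start, out):
    """pava() inner loop on caller-owned scratch; returns ``out``."""
    n = y.shape[0]
    k = -1
    for i in range(n):
        k += 1
        level[k] = y[i]
        weight[k] = 1.0
        start[k] = i
        while k > 0 and level[k - 1] >= level[k]:
            tot = weight[k - 1] + weight[k]
            level[k - 1] = (weight[k - 1] * level[k - 1] + weight[k] * level[k]) / tot
            weight[k - 1] = tot
            k -= 1
    for b in range(k + 1):
        end = start[b + 1] if b < k else n
        for i in range(start[b], end):
            out[i] = level[b]
    return out


@njit(cache=True)
def pava(y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit to ``y`` (unit weights).

    Standard pool-adjacent-violators with a block stack; O(n).
    """
    n = y.shape[0]
    return _pava_work(y, np.empty(n), np.empty(n), np.empty(n, np.int64),
                      np.empty(n))


@njit(cache=True)
def condensed_distances(X: np.ndarray, out: np.ndarray) -> None:
    """Pairwise Euclidean distances of 2-D configuration X in condensed order."""
    n = X.shape[0]
    k = 0
    for i in range(n):
        xi0 = X[i, 0]
        xi1 = X[i, 1]
        for j in range(i + 1, n):
            d0 = xi0 - X[j, 0]
            d1 = xi1 - X[j, 1]
            out[k] = np.sqrt(d0 * d0 + d1 * d1)
            k += 1


def pack_pairs(n: int) -> np.ndarray:
    """Packed (i << 32 | j) site pairs in condensed order."""
    iu, ju = np.triu_indices(n, 1)
    return (iu.astype(np.int64) << 32) | ju.astype(np.int64)


@njit(cache=True)
def _resort_ties(gstart, gend, ybuf, ijbuf, tmpv, tmpi, bkt, counts):
    """Re-sort each dissimilarity tie group by current distance.

    Within a tie group the monotone fit is unconstrained, so ordering tied
    pairs by ascending configuration distance yields the primary-approach
    optimum.  The order is warm-started from the previous iteration: a group
    already ascending is left untouched (an O(k) check), a nearly sorted one
    is repaired by insertion sort, and the rest get a stable bucket sort
    (equal distances keep their current relative order).  ``ybuf`` (values)
    and ``ijbuf`` (packed pairs) move together; the scratch buffers are
    caller-owned and at least as long as the largest group (+2 for counts).
    """
    for g in range(gstart.shape[0]):
        s = gstart[g]
        e = gend[g]
        k = e - s
        descents = 0
        vmin = ybuf[s]
        vmax = vmin
        prev = vmin
        for t in range(s + 1, e):
            v = ybuf[t]
            if v < prev:
                descents += 1
            if v < vmin:
                vmin = v
            elif v > vmax:
                vmax = v
            prev = v
        if descents == 0 or vmax <= vmin:
            continue
        if descents <= 1 + k // 8:
            # nearly sorted: adaptive insertion sort in place
            for i in range(s + 1, e):
                key = ybuf[i]
                item = ijbuf[i]
                j = i - 1
                while j >= s and ybuf[j] > key:
                    ybuf[j + 1] = ybuf[j]
                    ijbuf[j + 1] = ijbuf[j]
                    j -= 1
                ybuf[j + 1] = key
                ijbuf[j + 1] = item
            continue
        scale = (k - 1) / (vmax - vmin)
        for t in range(k):
            b = int((ybuf[s + t] - vmin) * scale)
            if b >= k:
                b = k - 1
            bkt[t] = b
        for b in range(k + 1):
            counts[b] = 0
        for t in range(k):
            counts[bkt[t] + 1] += 1
        for b in range(k):
            counts[b + 1] += counts[b]
        for t in range(k):  # stable distribute of (value, pair) records
            b = bkt[t]
            tmpv[counts[b]] = ybuf[s + t]
            tmpi[counts[b]] = ijbuf[s + t]
            counts[b] += 1
        # restore bucket starts, then insertion-sort inside each bucket
        for b in range(k, 0, -1):
            counts[b] = counts[b - 1]
        counts[0] = 0
        for b in range(k):
            lo = counts[b]
            hi = counts[b + 1]
            for i in range(lo + 1, hi):
                key = tmpv[i]
                item = tmpi[i]
                j = i - 1
                while j >= lo and tmpv[j] > key:
                    tmpv[j + 1] = tmpv[j]
                    tmpi[j + 1] = tmpi[j]
                    j -= 1
                tmpv[j + 1] = key
                tmpi[j + 1] = item
        for t in range(k):
            ybuf[s + t] = tmpv[t]
            ijbuf[s + t] = tmpi[t]


@njit(cache=True)
def smacof_start(X0, dvec_sorted, ijbuf0, gstart, gend, Vinv, m_end,
                 metric_weight, max_iter, tol):
    """Run one multistart replicate of (H)MDS from configuration X0.

    ``dvec_sorted`` are the dissimilarities in ascending order, ``ijbuf0``
    the matching packed site pairs; the first ``m_end`` sorted positions lie
    below the hybrid threshold and receive the metric term.  Returns (X, loss_history,
    n_iter, converged, final_stress1).  The loss history is the normalized
    composite loss sqrt((SS_nonmetric + w*SS_metric)/SS_dist), which for w=0
    is exactly Kruskal stress-1; it is non-increasing up to the convergence
    tolerance.
    """
    n = X0.shape[0]
    npair = dvec_sorted.shape[0]
    X = X0.copy()
    Y = np.empty((n, 2))
    ybuf = np.empty(npair)
    ijbuf = ijbuf0.copy()
    w_level = np.empty(npair)
    w_weight = np.empty(npair)
    w_start = np.empty(npair, np.int64)
    w_out = np.empty(npair)
    tmpv = np.empty(npair)
    tmpi = np.empty(npair, np.int64)
    bkt = np.empty(npair, np.int64)
    counts = np.empty(npair + 2, np.int64)
    loss_hist = np.empty(max_iter)
    sum_dvec2 = 0.0
    for k in range(npair):
        sum_dvec2 += dvec_sorted[k] * dvec_sorted[k]
    prev = np.inf
    converged = False
    stress1 = 1.0
    it = 0
    for it in range(max_iter):
        # current configuration distance for every ordered position
        for t in range(npair):
            ij = ijbuf[t]
            i = ij >> 32
            j = ij & _LOW32
            d0 = X[i, 0] - X[j, 0]
            d1 = X[i, 1] - X[j, 1]
            ybuf[t] = np.sqrt(d0 * d0 + d1 * d1)
        _resort_ties(gstart, gend, ybuf, ijbuf, tmpv, tmpi, bkt, counts)
        fit = _pava_work(ybuf, w_level, w_weight, w_start, w_out)
        denom = 0.0
        nm_num = 0.0
        for t in range(npair):
            denom += ybuf[t] * ybuf[t]
            r = ybuf[t] - fit[t]
            nm_num += r * r
        if denom < 1e-30:
            stress1 = 0.0
            loss_hist[it] = 0.0
            break
        # metric component: least-squares scale s for dist ~ s * delta;
        # the mask is a prefix of the sorted domain
        met_num = 0.0
        s = 0.0
        if metric_weight > 0.0:
            sn = 0.0
            sd = 0.0
            for t in range(m_end):
                sn += ybuf[t] * dvec_sorted[t]
                sd += dvec_sorted[t] * dvec_sorted[t]
            if sd > 0.0:
                s = sn / sd
            for t in range(m_end):
                r = ybuf[t] - s * dvec_sorted[t]
                met_num += r * r
        stress1 = np.sqrt(nm_num / denom)
        loss = np.sqrt((nm_num + metric_weight * met_num) / denom)
        loss_hist[it] = loss
        if prev - loss < tol * prev:
            converged = True
            break
        prev = loss
        if loss < 1e-12:
            converged = True
            break
        # weighted Guttman transform, accumulated pairwise: X <- Vinv @ Y with
        # Y[i] = sum_j w t_ij / d_ij * (X[i] - X[j])
        for i in range(n):
            Y[i, 0] = 0.0
            Y[i, 1] = 0.0
        for t in range(npair):
            d = ybuf[t]
            if d <= 1e-30:
                continue
            if t < m_end:
                w = 1.0 + metric_weight
                c = (fit[t] + metric_weight * s * dvec_sorted[t]) / d
            else:
                c = fit[t] / d
            ij = ijbuf[t]
            i = ij >> 32
            j = ij & _LOW32
            d0 = c * (X[i, 0] - X[j, 0])
            d1 = c * (X[i, 1] - X[j, 1])
            Y[i, 0] += d0
            Y[i, 1] += d1
            Y[j, 0] -= d0
            Y[j, 1] -= d1
        X = np.dot(Vinv, Y)
        # the configuration scale is arbitrary (stress-1 is scale-invariant)
        # and the update contracts it on weakly structured data; re-pin it so
        # the summed squared distances match the summed squared
        # dissimilarities, which prevents collapse to the origin
        c0 = 0.0
        c1 = 0.0
        for i in range(n):
            c0 += X[i, 0]
            c1 += X[i, 1]
        c0 /= n
        c1 /= n
        ss = 0.0
        for i in range(n):
            x0 = X[i, 0] - c0
            x1 = X[i, 1] - c1
            X[i, 0] = x0
            X[i, 1] = x1
            ss += x0 * x0 + x1 * x1
        ss *= n  # sum over pairs of squared distances
        if ss > 1e-300 and sum_dvec2 > 0.0:
            f = np.sqrt(sum_dvec2 / ss)
            for i in range(n):
                X[i, 0] *= f
                X[i, 1] *= f
    n_done = it + 1
    return X, loss_hist[:n_done].copy(), n_done, converged, stress1
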