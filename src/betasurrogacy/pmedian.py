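"""p-median site selection over ordination space.

A regular lattice of demand points is laid over the bounding box of the
ordinated sites; selecting the ``p`` sites that minimise the total
demand-point-to-nearest-selected-site distance yields a selection that spans
beta-diversity space.  The heuristic is a multistart hybrid: randomized
(sampled) greedy construction, vertex-substitution local search, and
path-relinking among the best local optima — the design of the classic hybrid
facility-location heuristics.  A deterministic full-greedy start is always
included, so the result can never be worse than greedy construction alone.
An exhaustive-enumeration solver provides the exact optimum on small
instances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from . import _pmedian_kernels as K
from ._seeds import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "DemandGrid",
    "SelectionResult",
    "make_demand_grid",
    "pmedian_objective",
    "select_pmedian",
    "select_pmedian_exact",
    "greedy_pmedian",
]


@dataclass(frozen=True)
class DemandGrid:
    """resolution x resolution lattice spanning the site bounding box."""

    points: np.ndarray
    resolution: int
    bounds: tuple  # (xmin, xmax, ymin, ymax)

    @property
    def m(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple
    p: int
    objective: float
    method: str
    n_starts: int = 0
    seed: int | None = None


def _as_coords(ordination_or_coords) -> np.ndarray:
    coords = getattr(ordination_or_coords, "coordinates", ordination_or_coords)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("site coordinates must be n x 2")
    return coords


def make_demand_grid(ordination_or_coords, resolution: int = 100) -> DemandGrid:
    """Regular grid of ``resolution**2`` demand points over the site bounding box."""
    coords = _as_coords(ordination_or_coords)
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    if xmax - xmin <= 0 or ymax - ymin <= 0:
        raise ValueError("degenerate ordination: zero extent on an axis")
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    XX, YY = np.meshgrid(xs, ys)
    points = np.column_stack([XX.ravel(), YY.ravel()])
    return DemandGrid(points=points, resolution=resolution,
                      bounds=(float(xmin), float(xmax), float(ymin), float(ymax)))


def pmedian_objective(selected, grid: DemandGrid, coords, chunk: int = 16384) -> float:
    """Total distance from every demand point to its nearest selected site.

    Demand points are processed in chunks, so no full m x n distance matrix
    is ever materialised.
    """
    coords = _as_coords(coords)
    sel = np.asarray(sorted(set(int(s) for s in selected)), dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if sel.min() < 0 or sel.max() >= coords.shape[0]:
        raise ValueError("selection indices out of range")
    total = 0.0
    site_xy = coords[sel]
    pts = grid.points
    for start in range(0, pts.shape[0], chunk):
        block = pts[start:start + chunk]
        total += float(cdist(block, site_xy).min(axis=1).sum())
    return total


def _distance_matrix(grid: DemandGrid, coords: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(cdist(grid.points, coords))


def _run_local_search(D, sel):
    m, n = D.shape
    sel = np.sort(np.asarray(sel, dtype=np.int64))
    insol = np.zeros(n, dtype=np.bool_)
    insol[sel] = True
    d1 = np.empty(m)
    d2 = np.empty(m)
    a1 = np.empty(m, np.int64)
    a2 = np.empty(m, np.int64)
    gain = np.empty(n)
    extra = np.empty((n, n))
    K.assign_all(D, sel, d1, d2, a1, a2)
    K.build_gain_extra(D, d1, d2, a1, gain, extra)
    eps = 1e-9 * (1.0 + d1.sum() / max(m, 1))
    K.local_search(D, sel, insol, d1, d2, a1, a2, gain, extra, eps,
                   max_swaps=200 + 4 * sel.size)
    K.assign_all(D, sel, d1, d2, a1, a2)
    return np.sort(sel), float(d1.sum())


def greedy_pmedian(coords, grid: DemandGrid, p: int) -> SelectionResult:
    """Deterministic greedy construction only (no local search)."""
    coords = _as_coords(coords)
    n = coords.shape[0]
    if not 1 <= p <= n:
        raise ValueError(f"p must be in 1..{n}")
    DT = np.ascontiguousarray(_distance_matrix(grid, coords).T)
    rows = np.tile(np.arange(n, dtype=np.int64), (p, 1))
    sel = K.greedy_construct(DT, p, rows)
    return SelectionResult(selected=tuple(int(s) for s in sel), p=p,
                           objective=pmedian_objective(sel, grid, coords),
                           method="greedy")


def select_pmedian(coords, grid: DemandGrid, p: int, n_starts: int = 32,
                   pool: int = 10, seed: int = 0) -> SelectionResult:
    """Multistart hybrid heuristic p-median selection.

    ``n_starts`` sampled-greedy constructions each refined by swap local
    search; the best ``pool`` distinct local optima are hybridized by
    path-relinking, and every relink product is itself refined.  Deterministic
    under ``seed`` (start ``k`` uses the same stream regardless of
    ``n_starts``).
    """
    coords = _as_coords(coords)
    n = coords.shape[0]
    if p == 0:
        raise ValueError("p must be at least 1")
    if not 1 <= p <= n:
        raise ValueError(f"p={p} out of range 1..{n}")
    if p == n:
        sel = tuple(range(n))
        return SelectionResult(selected=sel, p=p,
                               objective=pmedian_objective(sel, grid, coords),
                               method="all-sites", n_starts=n_starts, seed=seed)
    D = _distance_matrix(grid, coords)
    DT = np.ascontiguousarray(D.T)
    q = max(2, int(math.ceil(math.log2(n + 1))))

    candidates = []  # (objective, tuple(sel))

    def consider(sel, obj):
        candidates.append((obj, tuple(int(s) for s in sel)))

    # deterministic full greedy + local search (guarantees <= greedy-only)
    rows = np.tile(np.arange(n, dtype=np.int64), (p, 1))
    sel0 = K.greedy_construct(DT, p, rows)
    consider(*_run_local_search(D, sel0))

    for s_idx in range(n_starts):
        rng = stage_rng(seed, f"pmedian-start-{s_idx}")
        cand_rows = rng.integers(0, n, size=(p, q)).astype(np.int64)
        sel0 = K.greedy_construct(DT, p, cand_rows)
        consider(*_run_local_search(D, sel0))

    # elite pool: best distinct local optima
    seen = set()
    elite = []
    for obj, sel in sorted(candidates):
        if sel not in seen:
            seen.add(sel)
            elite.append((obj, sel))
        if len(elite) >= pool:
            break

    if len(elite) > 1:
        m = D.shape[0]
        d1 = np.empty(m)
        d2 = np.empty(m)
        a1 = np.empty(m, np.int64)
        a2 = np.empty(m, np.int64)
        gain = np.empty(n)
        extra = np.empty((n, n))
        insol = np.zeros(n, dtype=np.bool_)
        # star topology: relink the incumbent with every other elite solution
        for j in range(1, len(elite)):
            for i in (0,):
                obj_i, sel_i = elite[i]
                obj_j, sel_j = elite[j]
                # walk from the worse solution toward the better one
                start, guide = (sel_j, sel_i) if obj_i <= obj_j else (sel_i, sel_j)
                if set(start) == set(guide):
                    continue
                best_sel, _ = K.path_relink(
                    D, np.sort(np.asarray(start, np.int64)),
                    np.sort(np.asarray(guide, np.int64)),
                    insol, d1, d2, a1, a2, gain, extra)
                consider(*_run_local_search(D, best_sel))

    best_obj = min(obj for obj, _ in candidates)
    eps = 1e-9 * (1.0 + best_obj)
    best_sel = min(sel for obj, sel in candidates if obj <= best_obj + eps)
    return SelectionResult(selected=best_sel, p=p,
                           objective=pmedian_objective(best_sel, grid, coords),
                           method="hybrid-heuristic", n_starts=n_starts, seed=seed)


def select_pmedian_exact(coords, grid: DemandGrid, p: int,
                         max_combinations: int = 10 ** 6) -> SelectionResult:
    """Exhaustive-enumeration global optimum (test oracle for small instances).

    Ties are broken by the lexicographically smallest index set.
    """
    coords = _as_coords(coords)
    n = coords.shape[0]
    if not 1 <= p <= n:
        raise ValueError(f"p must be in 1..{n}")
    n_comb = math.comb(n, p)
    if n_comb > max_combinations:
        raise ValueError(f"C({n},{p}) = {n_comb} combinations exceed "
                         f"{max_combinations}; use select_pmedian instead")
    D = _distance_matrix(grid, coords)
    best = None
    best_sel = None
    for subset in combinations(range(n), p):
        obj = float(D[:, subset].min(axis=1).sum())
        if best is None or obj < best - 1e-12:
            best = obj
            best_sel = subset
    return SelectionResult(selected=best_sel, p=p,
                           objective=pmedian_objective(best_sel, grid, coords),
                           method="exact")
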