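"""Optimal and random benchmarks for species representation.

The Species Accumulation Index compares a surrogate selection against two
reference curves built from the occurrence matrix itself:

* ``O`` — the largest number of species representable in ``p`` sites.  Exact
  maximal coverage is NP-hard, so O is computed exactly by enumeration when
  the instance is small and otherwise estimated as the better of two
  complementary heuristics: forward greedy coverage, and the retained tail of
  a backward "core-area" removal ranking (the rule used by cell-removal
  reserve-selection software: repeatedly discard the site least needed to
  keep at least one occurrence of every species).
* ``R`` — the mean number of species represented in ``p`` randomly chosen
  sites, with a percentile 95% confidence band over replicate orderings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seeds import stage_rng
from .community import OccurrenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RemovalOrder",
    "RandomBaseline",
    "species_represented",
    "greedy_max_coverage",
    "core_area_removal",
    "optimal_curve",
    "random_accumulation",
]


@dataclass(frozen=True)
class RemovalOrder:
    """Backward-removal ranking: first element removed first, last kept longest."""

    order: tuple
    removal_values: tuple

    def retained(self, k: int) -> tuple:
        """The k sites kept longest (the reserve of size k)."""
        if not 0 <= k <= len(self.order):
            raise ValueError("k out of range")
        return tuple(sorted(self.order[len(self.order) - k:]))


@dataclass(frozen=True)
class RandomBaseline:
    """Random accumulation statistics per p.

    ``lo``/``hi`` are the 2.5th/97.5th percentiles of the replicate species
    counts (the band drawn around the random accumulation curve); ``se`` is
    the standard error of the mean R, whose 95% CI (R +/- 1.96 se) is the
    significance reference for surrogate selections.
    """

    p_list: tuple
    mean: tuple
    lo: tuple
    hi: tuple
    se: tuple
    n_reps: int
    seed: int

    def __post_init__(self):
        for lo, mean, hi in zip(self.lo, self.mean, self.hi):
            if not (lo - 1e-9 <= mean <= hi + 1e-9):
                raise ValueError("baseline percentiles must bracket the mean")

    def ci_hi(self) -> tuple:
        """Upper bound of the 95% CI on the mean R, per p."""
        return tuple(m + 1.959963984540054 * s for m, s in zip(self.mean, self.se))


def species_represented(m: OccurrenceMatrix, selected) -> int:
    """Number of species present in at least one selected site."""
    sel = sorted(set(int(s) for s in selected))
    if not sel:
        return 0
    if sel[0] < 0 or sel[-1] >= m.n_sites:
        raise ValueError("selection indices out of range")
    return int(m.presence[sel].any(axis=0).sum())


def greedy_max_coverage(m: OccurrenceMatrix, p: int):
    """Forward greedy maximal coverage.

    Adds, at each step, the site contributing the most uncovered species
    (ties -> lowest site index).  Returns ``(selected, coverage_per_step)``
    with coverage after each addition (non-decreasing).
    """
    n = m.n_sites
    if not 1 <= p <= n:
        raise ValueError(f"p must be in 1..{n}")
    P = m.presence
    covered = np.zeros(m.n_species, dtype=bool)
    chosen = np.zeros(n, dtype=bool)
    selected = []
    coverage = []
    for _ in range(p):
        gains = (P & ~covered).sum(axis=1)
        gains[chosen] = -1
        site = int(np.argmax(gains))  # first max -> lowest index
        chosen[site] = True
        covered |= P[site]
        selected.append(site)
        coverage.append(int(covered.sum()))
    return tuple(selected), tuple(coverage)


def core_area_removal(m: OccurrenceMatrix) -> RemovalOrder:
    """Backward greedy cell-removal ranking.

    Each remaining site i is valued at ``v_i = max_{j in i} 1 / r_j`` where
    ``r_j`` counts remaining sites holding species j; the lowest-valued site
    (the one whose rarest species is most redundant) is removed first, ties
    -> lowest index.  A site holding a species' last occurrence has v = 1 and
    survives as long as possible.
    """
    P = m.presence
    n = P.shape[0]
    remaining = np.ones(n, dtype=bool)
    order = []
    values = []
    for _ in range(n):
        idxs = np.flatnonzero(remaining)
        sub = P[idxs]
        r = sub.sum(axis=0)
        with np.errstate(divide="ignore"):
            rr = np.where(sub, r[None, :], np.inf)
        minr = rr.min(axis=1)
        v = np.where(np.isfinite(minr), 1.0 / minr, 0.0)  # empty site -> 0, removed first
        local = int(np.argmin(v))  # first min -> lowest site index
        site = int(idxs[local])
        order.append(site)
        values.append(float(v[local]))
        remaining[site] = False
    return RemovalOrder(order=tuple(order), removal_values=tuple(values))


def _exact_max_coverage(m: OccurrenceMatrix, p: int) -> int:
    """Exhaustive maximal coverage via bitset unions (small instances only)."""
    masks = []
    for row in m.presence:
        v = 0
        for j in np.flatnonzero(row):
            v |= 1 << int(j)
        masks.append(v)
    best = 0
    from itertools import combinations
    for subset in combinations(range(m.n_sites), p):
        u = 0
        for i in subset:
            u |= masks[i]
        c = u.bit_count()
        if c > best:
            best = c
            if best == m.n_species:
                break
    return best


def optimal_curve(m: OccurrenceMatrix, p_list: Sequence[int],
                  removal: RemovalOrder | None = None,
                  exact_limit: int = 20_000) -> tuple:
    """Estimated optimum O(p) for each p.

    O must be the best lower bound on true maximal coverage we can compute:
    when the instance is small enough (C(n, p) <= ``exact_limit``
    combinations) the optimum is found by exhaustive enumeration; otherwise
    it is the better of two complementary heuristics — forward greedy
    coverage and the ``p`` sites retained longest by core-area removal —
    with a running maximum enforcing monotonicity in p.
    """
    p_list = [int(p) for p in p_list]
    n = m.n_sites
    if any(p < 1 or p > n for p in p_list):
        raise ValueError("p values must be in 1..n_sites")
    p_max = max(p_list)
    _, greedy_cov = greedy_max_coverage(m, p_max)
    removal = removal or core_area_removal(m)
    # coverage of the last-k retained sites, computed by a reversed scan
    rev = list(removal.order[::-1])
    covered = np.zeros(m.n_species, dtype=bool)
    retained_cov = np.zeros(n + 1, dtype=int)
    for k, site in enumerate(rev, start=1):
        covered |= m.presence[site]
        retained_cov[k] = int(covered.sum())
    by_p = {}
    for p in sorted(set(p_list)):
        o = max(greedy_cov[p - 1], int(retained_cov[p]))
        if o < m.n_species and math.comb(n, p) <= exact_limit:
            o = _exact_max_coverage(m, p)
        by_p[p] = o
    running = 0
    for p in sorted(by_p):  # the true optimum is non-decreasing in p
        running = max(running, by_p[p])
        by_p[p] = running
    return tuple(by_p[p] for p in p_list)


def random_accumulation(m: OccurrenceMatrix, p_list: Sequence[int],
                        n_reps: int = 1000, seed: int = 0) -> RandomBaseline:
    """Random baseline R: species counts for random site orderings.

    For each replicate a uniform random permutation of sites is drawn and the
    species count at every requested p is recorded; R is the replicate mean,
    the confidence band the 2.5th/97.5th percentile.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    p_list = [int(p) for p in p_list]
    n = m.n_sites
    if any(p < 1 or p > n for p in p_list):
        raise ValueError("p values must be in 1..n_sites")
    P = m.presence
    absent = ~P.any(axis=0)
    rng = stage_rng(seed, "random-accumulation")
    counts = np.empty((n_reps, len(p_list)), dtype=np.int64)
    ps = np.asarray(p_list)
    for rep in range(n_reps):
        perm = rng.permutation(n)
        first = np.argmax(P[perm], axis=0)  # first permuted site holding each species
        first[absent] = n
        counts[rep] = (first[None, :] < ps[:, None]).sum(axis=1)
    mean = counts.mean(axis=0)
    lo = np.percentile(counts, 2.5, axis=0)
    hi = np.percentile(counts, 97.5, axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n_reps)
    return RandomBaseline(p_list=tuple(p_list), mean=tuple(float(x) for x in mean),
                          lo=tuple(float(x) for x in lo),
                          hi=tuple(float(x) for x in hi),
                          se=tuple(float(x) for x in se),
                          n_reps=n_reps, seed=seed)
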