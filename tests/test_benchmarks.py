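"""Species representation benchmarks: greedy coverage, core-area removal,
random accumulation."""

from itertools import combinations

import numpy as np
import pytest

from betasurrogacy import (OccurrenceMatrix, core_area_removal,
                           greedy_max_coverage, optimal_curve,
                           random_accumulation, species_represented)
from conftest import random_occurrence


def _exhaustive_max_coverage(presence, p):
    n = presence.shape[0]
    return max(presence[list(s)].any(axis=0).sum()
               for s in combinations(range(n), p))


class TestSpeciesRepresented:
    def test_empty_selection(self, small_community):
        assert species_represented(small_community, []) == 0

    def test_all_sites_cover_everything(self, small_community):
        n = small_community.n_sites
        assert species_represented(small_community, range(n)) == \
            small_community.n_species

    def test_matches_set_union_oracle(self, rng, small_community):
        sel = list(rng.choice(small_community.n_sites, size=7, replace=False))
        union = set()
        for s in sel:
            union |= set(np.flatnonzero(small_community.presence[s]))
        assert species_represented(small_community, sel) == len(union)


class TestGreedyMaxCoverage:
    def test_hand_trace(self):
        # sites {a,b}, {b,c}, {d}: greedy takes site0 (2 new) then site1
        # (lowest index among 1-new ties); exhaustive optimum for p=2 is 3
        m = OccurrenceMatrix(["s1", "s2", "s3"], list("abcd"),
                             np.array([[1, 1, 0, 0],
                                       [0, 1, 1, 0],
                                       [0, 0, 0, 1]], bool))
        selected, coverage = greedy_max_coverage(m, 2)
        assert selected == (0, 1)
        assert coverage == (2, 3)
        assert _exhaustive_max_coverage(m.presence, 2) == 3

    def test_full_selection_covers_all(self, small_community):
        _, cov = greedy_max_coverage(small_community, small_community.n_sites)
        assert cov[-1] == small_community.n_species
        assert all(a <= b for a, b in zip(cov, cov[1:]))

    def test_approximation_guarantee(self):
        # greedy coverage >= (1 - 1/e) * exhaustive optimum
        for seed in range(15):
            rng = np.random.default_rng(300 + seed)
            m = random_occurrence(rng, int(rng.integers(5, 13)),
                                  int(rng.integers(4, 12)), density=0.25)
            p = int(rng.integers(1, 5))
            _, cov = greedy_max_coverage(m, p)
            opt = _exhaustive_max_coverage(m.presence, p)
            assert cov[-1] >= (1 - 1 / np.e) * opt - 1e-9


class TestCoreAreaRemoval:
    def test_hand_trace_duplicate_and_unique(self):
        # sites A={a}, B={a}, C={b}: r_a=2, r_b=1 so v_A=v_B=1/2, v_C=1;
        # A removed first (tie -> lowest index), then B (now v_B=1), C kept
        m = OccurrenceMatrix(["A", "B", "C"], ["a", "b"],
                             np.array([[1, 0], [1, 0], [0, 1]], bool))
        ro = core_area_removal(m)
        assert ro.order == (0, 1, 2)
        assert ro.removal_values == (0.5, 1.0, 1.0)

    def test_single_site(self):
        m = OccurrenceMatrix(["A"], ["a"], np.ones((1, 1), bool))
        assert core_area_removal(m).order == (0,)

    def test_retained_sets_are_nested_with_monotone_coverage(self, small_community):
        ro = core_area_removal(small_community)
        assert sorted(ro.order) == list(range(small_community.n_sites))
        prev = None
        coverages = []
        for k in range(small_community.n_sites, 0, -1):
            kept = set(ro.retained(k))
            if prev is not None:
                assert kept <= prev
            prev = kept
            coverages.append(species_represented(small_community, kept))
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))


class TestOptimalCurve:
    def test_full_landscape_reaches_total_richness(self, small_community):
        n = small_community.n_sites
        assert optimal_curve(small_community, [n]) == (small_community.n_species,)

    def test_matches_exhaustive_on_small_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            m = random_occurrence(rng, int(rng.integers(4, 11)),
                                  int(rng.integers(3, 10)), density=0.3)
            ps = list(range(1, m.n_sites + 1))
            got = optimal_curve(m, ps)
            expected = tuple(_exhaustive_max_coverage(m.presence, p) for p in ps)
            assert got == expected

    def test_monotone_in_p(self, small_community):
        curve = optimal_curve(small_community,
                              list(range(1, small_community.n_sites + 1)))
        assert all(a <= b for a, b in zip(curve, curve[1:]))


class TestRandomAccumulation:
    def test_full_landscape_has_zero_width(self, small_community):
        n = small_community.n_sites
        base = random_accumulation(small_community, [n], n_reps=50, seed=1)
        assert base.mean == (small_community.n_species,)
        assert base.lo == base.hi == base.mean

    def test_single_site_mean_matches_mean_richness(self, small_community):
        base = random_accumulation(small_community, [1], n_reps=1000, seed=2)
        expected = small_community.richness().mean()
        assert abs(base.mean[0] - expected) < 3 * base.se[0] + 1e-9

    def test_deterministic_under_seed(self, small_community):
        a = random_accumulation(small_community, [3, 7], n_reps=100, seed=5)
        c = random_accumulation(small_community, [3, 7], n_reps=100, seed=5)
        assert a == c

    def test_band_and_monotonicity(self, small_community):
        ps = [2, 5, 9, 14]
        base = random_accumulation(small_community, ps, n_reps=200, seed=3)
        for lo, mean, hi in zip(base.lo, base.mean, base.hi):
            assert lo <= mean <= hi
        assert all(a <= b for a, b in zip(base.mean, base.mean[1:]))
        assert all(a <= b for a, b in zip(base.lo, base.lo[1:]))
        assert all(a <= b for a, b in zip(base.hi, base.hi[1:]))

    def test_too_few_reps_rejected(self, small_community):
        with pytest.raises(ValueError):
            random_accumulation(small_community, [2], n_reps=1)


class TestOptimumDominatesRandom:
    def test_o_at_least_r_on_random_instances(self):
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            m = random_occurrence(rng, 20, 15, density=0.2)
            ps = [2, 5, 10, 15]
            o = optimal_curve(m, ps)
            base = random_accumulation(m, ps, n_reps=300, seed=seed)
            for ov, rv in zip(o, base.mean):
                assert ov >= rv - 1e-9
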