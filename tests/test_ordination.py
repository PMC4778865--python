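"""Monotone regression, Kruskal stress, and NMDS/HMDS recovery."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import betasurrogacy.ordination as ordmod
from betasurrogacy import (DissimilarityMatrix, OrdinationConfig,
                           best_ordination, hmds, monotone_regression, nmds,
                           stress1)


def _isotonic_oracle(y):
    """Exhaustive search over consecutive-block partitions (length <= 8)."""
    n = len(y)
    best_sse, best_fit = np.inf, None
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        fit = np.empty(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            fit[a:b] = np.mean(y[a:b])
        if np.all(np.diff(fit) >= -1e-12):
            sse = np.sum((fit - y) ** 2)
            if sse < best_sse:
                best_sse, best_fit = sse, fit
    return best_fit


def _euclidean_dissimilarity(points, scale=True):
    dvec = pdist(points)
    if scale:
        dvec = dvec / dvec.max()
    return DissimilarityMatrix(squareform(dvec),
                               [f"s{i}" for i in range(len(points))])


class TestMonotoneRegression:
    def test_identity_when_already_monotone(self):
        dist = np.array([1.0, 2.0, 3.5, 3.5, 7.0])
        diss = np.arange(5.0)
        assert np.allclose(monotone_regression(dist, diss), dist)

    def test_pools_adjacent_violators(self):
        fit = monotone_regression(np.array([3.0, 1.0]), np.array([0.0, 1.0]))
        assert np.allclose(fit, [2.0, 2.0])

    def test_tied_dissimilarities_are_unconstrained(self):
        # primary approach: within a tie group values are ordered by distance
        fit = monotone_regression(np.array([5.0, 1.0, 3.0]),
                                  np.array([1.0, 1.0, 2.0]))
        assert np.allclose(fit, [4.0, 1.0, 4.0])

    def test_matches_block_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            dist = rng.normal(size=n)
            diss = np.arange(float(n))  # strictly increasing: total order
            fit = monotone_regression(dist, diss)
            assert np.allclose(fit, _isotonic_oracle(dist), atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            monotone_regression(np.ones(3), np.ones(4))


class TestStress1:
    def test_perfect_configuration_has_zero_stress(self, rng):
        pts = rng.normal(size=(20, 2))
        d = _euclidean_dissimilarity(pts)
        assert stress1(pts, d) < 1e-6

    def test_all_zero_coordinates_rejected(self, rng):
        d = _euclidean_dissimilarity(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            stress1(np.zeros((5, 2)), d)

    def test_invariant_under_similarity_transforms(self, rng):
        pts = rng.normal(size=(15, 2))
        d = _euclidean_dissimilarity(rng.normal(size=(15, 2)))
        base = stress1(pts, d)
        theta = 0.83
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        R = np.array([[1.0, 0.0], [0.0, -1.0]])  # reflection
        for X in (pts @ Q, pts @ Q @ R, pts * 3.7, pts + [5.0, -2.0]):
            assert abs(stress1(X, d) - base) < 1e-9


class TestNMDS:
    def test_recovers_known_configuration(self, rng):
        truth = rng.uniform(size=(20, 2))
        d = _euclidean_dissimilarity(truth)
        res = nmds(d, OrdinationConfig(seed=7))
        assert res.stress < 0.01
        from scipy.spatial import procrustes
        _, aligned, _ = procrustes(truth, res.coordinates)
        t_norm = (truth - truth.mean(0)) / np.linalg.norm(truth - truth.mean(0))
        rmse = np.sqrt(np.mean((aligned - t_norm) ** 2))
        diameter = np.max(pdist(t_norm))
        assert rmse < 0.05 * diameter

    def test_deterministic_under_seed(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(12, 2)))
        a = nmds(d, OrdinationConfig(seed=3))
        c = nmds(d, OrdinationConfig(seed=3))
        assert np.array_equal(a.coordinates, c.coordinates)
        assert a.stress == c.stress

    def test_reported_stress_is_minimum_over_starts(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(10, 2)))
        res = nmds(d, OrdinationConfig(seed=5, n_starts=10))
        assert len(res.start_stresses) == 10
        assert res.stress == min(res.start_stresses)

    def test_three_sites_embed_almost_perfectly(self, rng):
        for _ in range(5):
            vals = rng.uniform(0.2, 1.0, size=3)
            # enforce triangle inequality to keep the input a metric
            vals = np.sort(vals)
            vals[2] = min(vals[2], vals[0] + vals[1] - 1e-3)
            d = DissimilarityMatrix(squareform(vals), ["a", "b", "c"])
            assert nmds(d, OrdinationConfig(seed=0)).stress < 1e-3

    def test_per_start_loss_nonincreasing(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(15, 2)))
        cfg = OrdinationConfig(seed=11)
        res = nmds(d, cfg)
        for hist in res.loss_histories:
            diffs = np.diff(hist)
            assert np.all(diffs <= cfg.tol * hist[:-1] + 1e-12)

    def test_coordinates_centered(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(12, 2)))
        res = nmds(d, OrdinationConfig(seed=2))
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)


class TestHMDS:
    def test_reduces_to_nmds_with_zero_metric_weight(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(12, 2)))
        cfg = OrdinationConfig(seed=9, hybrid_threshold=1.0, metric_weight=0.0)
        a = nmds(d, cfg)
        b = hmds(d, cfg)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_recovers_euclidean_input(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(20, 2)))
        res = hmds(d, OrdinationConfig(seed=4))
        assert res.stress < 0.01

    def test_handles_saturated_dissimilarities(self, rng):
        vals = squareform(rng.uniform(0.3, 0.9, size=15 * 14 // 2))
        sat = rng.random((15, 15)) < 0.3
        sat = np.triu(sat, 1)
        vals[sat | sat.T] = 1.0
        np.fill_diagonal(vals, 0)
        d = DissimilarityMatrix(vals, [f"s{i}" for i in range(15)])
        res = hmds(d, OrdinationConfig(seed=6))
        assert np.isfinite(res.stress) and 0 <= res.stress <= 1

    def test_warns_when_no_pair_below_threshold(self, rng):
        vals = np.ones((5, 5)) - np.eye(5)
        d = DissimilarityMatrix(vals, list("abcde"))
        with pytest.warns(UserWarning, match="hybrid_threshold"):
            hmds(d, OrdinationConfig(seed=1, hybrid_threshold=0.5, n_starts=2,
                                     max_iter=50))


class TestBestOrdination:
    def test_returns_lower_stress_method(self, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(15, 2)))
        res = best_ordination(d, OrdinationConfig(seed=8))
        rn = nmds(d, OrdinationConfig(seed=8))
        rh = hmds(d, OrdinationConfig(seed=8))
        assert res.stress == min(rn.stress, rh.stress)
        expected = "hmds" if rh.stress < rn.stress else "nmds"
        assert res.method == expected

    def test_tie_prefers_nmds(self, monkeypatch, rng):
        d = _euclidean_dissimilarity(rng.uniform(size=(6, 2)))
        fake = nmds(d, OrdinationConfig(seed=1, n_starts=2, max_iter=50))
        monkeypatch.setattr(ordmod, "hmds",
                            lambda *_a, **_k: ordmod.OrdinationResult(
                                coordinates=fake.coordinates, stress=fake.stress,
                                method="hmds", start_stresses=(fake.stress,),
                                converged=(True,)))
        monkeypatch.setattr(ordmod, "nmds", lambda *_a, **_k: fake)
        assert best_ordination(d).method == "nmds"
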