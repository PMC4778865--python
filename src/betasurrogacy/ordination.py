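"""Nonmetric and hybrid multidimensional scaling of beta diversity.

Sites are placed in 2-D so that inter-site distance reflects Jaccard
dissimilarity.  NMDS minimizes Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where the disparities dhat are the least-squares monotone (isotonic) fit of
configuration distance on dissimilarity, ties handled by Kruskal's primary
approach (tied dissimilarities unconstrained among themselves).  HMDS adds a
metric least-squares term for pairs whose dissimilarity lies below a
threshold: large Jaccard dissimilarities saturate at 1 and carry only rank
information, while small ones are close to ratio-scale, so anchoring them
metrically can stabilise the configuration.

Each method restarts ``n_starts`` times (first start from classical metric
scaling, the rest random) for up to ``max_iter`` majorization iterations, and
keeps the configuration with the lowest stress.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._mds_kernels import (condensed_distances, pack_pairs, pava,
                           smacof_start)
from ._seeds import stage_rng
from .community import DissimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationConfig",
    "OrdinationResult",
    "monotone_regression",
    "stress1",
    "nmds",
    "hmds",
    "best_ordination",
]


@dataclass(frozen=True)
class OrdinationConfig:
    method: str = "nmds"
    n_dims: int = 2
    n_starts: int = 10
    max_iter: int = 1000
    tol: float = 1e-6
    hybrid_threshold: float = 0.9
    metric_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("nmds", "hmds"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_dims != 2:
            raise ValueError("only 2-D ordinations are supported")
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be >= 1")
        if not (0 < self.hybrid_threshold <= 1):
            raise ValueError("hybrid_threshold must be in (0, 1]")


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    method: str
    start_stresses: tuple
    converged: tuple
    loss_histories: tuple = field(repr=False, default=())

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]


def monotone_regression(distances: np.ndarray, dissimilarities: np.ndarray) -> np.ndarray:
    """Least-squares monotone fit of ``distances`` on the dissimilarity order.

    Tied dissimilarities are unconstrained among themselves (primary
    approach): within each tie group the values are taken in ascending
    distance order, which makes plain pool-adjacent-violators optimal.
    """
    distances = np.asarray(distances, dtype=float)
    dissimilarities = np.asarray(dissimilarities, dtype=float)
    if distances.shape != dissimilarities.shape or distances.ndim != 1:
        raise ValueError("distances and dissimilarities must be equal-length vectors")
    if not np.all(np.isfinite(distances)):
        raise ValueError("distances must be finite")
    order = np.lexsort((distances, dissimilarities))
    fit = pava(distances[order])
    out = np.empty_like(fit)
    out[order] = fit
    return out


def _condensed(coords: np.ndarray) -> np.ndarray:
    coords = np.ascontiguousarray(coords, dtype=float)
    n = coords.shape[0]
    out = np.empty(n * (n - 1) // 2)
    condensed_distances(coords, out)
    return out


def stress1(coordinates: np.ndarray, d: DissimilarityMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (d.n, 2):
        raise ValueError(f"coordinates must be {d.n} x 2")
    if np.allclose(coordinates, 0):
        raise ValueError("degenerate all-zero configuration")
    dist = _condensed(coordinates)
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        raise ValueError("degenerate configuration: all points coincide")
    dhat = monotone_regression(dist, d.condensed())
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _classical_scaling(values: np.ndarray) -> np.ndarray:
    """Torgerson metric scaling; first-start initialization."""
    n = values.shape[0]
    J = np.eye(n) - 1.0 / n
    Bmat = -0.5 * J @ (values ** 2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    X = np.empty((n, 2))
    for k, idx in enumerate((n - 1, n - 2)):
        lam = vals[idx]
        if lam > 1e-12:
            X[:, k] = vecs[:, idx] * np.sqrt(lam)
        else:
            # rank-deficient input: deterministic jitter keeps the axis alive
            X[:, k] = np.linspace(-1e-4, 1e-4, n)
    return X


def _tie_groups(dvec: np.ndarray):
    order0 = np.argsort(dvec, kind="stable")
    sorted_vals = dvec[order0]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [dvec.size]))
    big = (ends - starts) > 1
    singles = starts[~big].astype(np.int64)  # singleton-value positions
    return order0, starts[big].astype(np.int64), ends[big].astype(np.int64), singles


def _laplacian_pinv(n: int, mask: np.ndarray, metric_weight: float) -> np.ndarray:
    W = np.ones((n, n))
    if metric_weight > 0:
        from scipy.spatial.distance import squareform
        W = W + metric_weight * squareform(mask.astype(float))
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    return np.linalg.pinv(L)


def _orient(X: np.ndarray) -> np.ndarray:
    """Center and fix reflection: the largest-|value| entry of each axis is positive."""
    X = X - X.mean(axis=0)
    for k in range(X.shape[1]):
        idx = int(np.argmax(np.abs(X[:, k])))
        if X[idx, k] < 0:
            X[:, k] = -X[:, k]
    return X


def _run_mds(d: DissimilarityMatrix, cfg: OrdinationConfig, metric_weight: float,
             method: str) -> OrdinationResult:
    n = d.n
    if n < 3:
        raise ValueError("ordination requires at least 3 sites")
    dvec = d.condensed()
    order0, gstart, gend, _singles = _tie_groups(dvec)
    if metric_weight > 0:
        mask = dvec < cfg.hybrid_threshold
        if not mask.any():
            warnings.warn("no pair below hybrid_threshold; HMDS reduces to NMDS",
                          stacklevel=3)
    else:
        mask = np.zeros_like(dvec, dtype=bool)
    Vinv = _laplacian_pinv(n, mask, metric_weight)
    ijbuf0 = pack_pairs(n)[order0]
    dvec_sorted = dvec[order0]
    # below-threshold pairs occupy a prefix of the sorted domain
    m_end = int(np.searchsorted(dvec_sorted, cfg.hybrid_threshold,
                                side="left")) if metric_weight > 0 else 0
    scale = float(np.mean(dvec)) or 1.0

    best = None
    stresses = []
    conv_flags = []
    histories = []
    for s_idx in range(cfg.n_starts):
        if s_idx == 0:
            X0 = _classical_scaling(d.values)
        else:
            rng = stage_rng(cfg.seed, f"{method}-start-{s_idx}")
            X0 = rng.standard_normal((n, 2)) * scale
        X, hist, n_iter, converged, _ = smacof_start(
            np.ascontiguousarray(X0), dvec_sorted, ijbuf0, gstart, gend,
            Vinv, m_end, float(metric_weight), int(cfg.max_iter),
            float(cfg.tol))
        stress = stress1(X, d) if not np.allclose(X, 0) else 1.0
        stresses.append(stress)
        conv_flags.append(bool(converged))
        histories.append(hist)
        if best is None or stress < best[0]:
            best = (stress, X)
    if not any(conv_flags):
        warnings.warn(f"{method}: no start converged within {cfg.max_iter} "
                      "iterations; returning best configuration anyway",
                      stacklevel=3)
    coords = _orient(best[1])
    return OrdinationResult(coordinates=coords, stress=float(min(stresses)),
                            method=method, start_stresses=tuple(stresses),
                            converged=tuple(conv_flags),
                            loss_histories=tuple(histories))


def nmds(d: DissimilarityMatrix, cfg: OrdinationConfig | None = None) -> OrdinationResult:
    """Nonmetric MDS: best of ``cfg.n_starts`` majorization runs."""
    cfg = cfg or OrdinationConfig(method="nmds")
    return _run_mds(d, cfg, metric_weight=0.0, method="nmds")


def hmds(d: DissimilarityMatrix, cfg: OrdinationConfig | None = None) -> OrdinationResult:
    """Hybrid MDS: nonmetric stress plus a metric term for unsaturated pairs."""
    cfg = cfg or OrdinationConfig(method="hmds")
    return _run_mds(d, cfg, metric_weight=cfg.metric_weight, method="hmds")


def best_ordination(d: DissimilarityMatrix, cfg: OrdinationConfig | None = None) -> OrdinationResult:
    """Run NMDS and HMDS, return whichever achieves the lower stress.

    Ties favour NMDS (the simpler model).
    """
    cfg = cfg or OrdinationConfig()
    res_n = nmds(d, replace(cfg, method="nmds"))
    res_h = hmds(d, replace(cfg, method="hmds"))
    chosen = res_h if res_h.stress < res_n.stress else res_n
    logger.info("best_ordination: nmds stress %.4f, hmds stress %.4f -> %s",
                res_n.stress, res_h.stress, chosen.method)
    return chosen
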