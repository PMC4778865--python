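"""Synthetic communities with unimodal niche structure, plus null controls.

The surrogacy argument rests on one assumption: species have unimodal
occurrence responses along environmental gradients, so sites far apart in
composition are also far apart environmentally, and a selection spanning
compositional space samples many distinct niches.  This module instantiates
that assumption directly: sites get positions on two gradients in [0, 1]^2,
each species j a Gaussian response surface

    pi_ij = h_j * exp(-0.5 * [((e_i1 - mu_j1)/sigma_j1)^2
                              + ((e_i2 - mu_j2)/sigma_j2)^2])

and presences are independent Bernoulli(pi_ij) draws.  The null generator
breaks the assumption (presence probability independent of environment) and
serves as the negative control: on null data the pipeline should score no
better than random.

Reference parameters (300 sites x 150 species, sigma ~ U(0.05, 0.25),
h ~ U(0.5, 1), mu ~ U(0, 1)^2) give communities of realistic sparsity
(median species occupancy of a few percent) with strong gradient structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .community import OccurrenceMatrix, read_occurrences, write_occurrences

logger = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_PARAMS",
    "NicheParams",
    "SyntheticCommunity",
    "occurrence_probabilities",
    "generate_unimodal",
    "generate_null",
    "regenerate_presence",
    "coarsen_to_atlas",
    "write_fixture",
    "read_fixture",
]

#: reference generating conditions for recovery experiments
REFERENCE_PARAMS = dict(n_sites=300, n_species=150,
                        sigma_range=(0.05, 0.25), h_range=(0.5, 1.0))


@dataclass(frozen=True)
class NicheParams:
    """Per-species Gaussian niche: optimum mu, tolerance sigma, peak height h."""

    mu: np.ndarray      # (n_species, 2), gradient units
    sigma: np.ndarray   # (n_species, 2), > 0
    h: np.ndarray       # (n_species,), peak occurrence probability in (0, 1]

    def __post_init__(self):
        mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "h", h)
        s = h.shape[0]
        if mu.shape != (s, 2) or sigma.shape != (s, 2):
            raise ValueError("mu and sigma must be (n_species, 2)")
        if np.any(sigma <= 0):
            raise ValueError("sigma components must be strictly positive")
        if np.any((h <= 0) | (h > 1)):
            raise ValueError("h must lie in (0, 1]")

    @property
    def n_species(self) -> int:
        return self.h.shape[0]


@dataclass(frozen=True)
class SyntheticCommunity:
    occurrences: OccurrenceMatrix
    environment: np.ndarray          # (n_sites, 2)
    truth: object                    # NicheParams, or occupancy vector for null
    seed: int
    kind: str                        # "unimodal" | "null"

    def __post_init__(self):
        env = np.asarray(self.environment, dtype=float)
        object.__setattr__(self, "environment", env)
        if env.shape != (self.occurrences.n_sites, 2):
            raise ValueError("environment must be (n_sites, 2)")


def occurrence_probabilities(truth: NicheParams, environment: np.ndarray) -> np.ndarray:
    """Gaussian-response occurrence probability matrix pi (n_sites x n_species)."""
    env = np.asarray(environment, dtype=float)
    z1 = (env[:, [0]] - truth.mu[:, 0][None, :]) / truth.sigma[:, 0][None, :]
    z2 = (env[:, [1]] - truth.mu[:, 1][None, :]) / truth.sigma[:, 1][None, :]
    return truth.h[None, :] * np.exp(-0.5 * (z1 ** 2 + z2 ** 2))


def _site_ids(n):
    return [f"s{i + 1:04d}" for i in range(n)]


def _species_ids(s):
    return [f"sp{j + 1:04d}" for j in range(s)]


def _environment(n_sites, env_model, rng):
    if env_model == "uniform":
        return rng.uniform(0.0, 1.0, size=(n_sites, 2))
    if env_model == "gradient-correlated":
        e1 = rng.uniform(0.0, 1.0, size=n_sites)
        e2 = np.clip(0.5 * e1 + 0.5 * rng.uniform(0.0, 1.0, size=n_sites), 0.0, 1.0)
        return np.column_stack([e1, e2])
    raise ValueError(f"unknown env_model {env_model!r}")


def generate_unimodal(n_sites: int = 300, n_species: int = 150,
                      env_model: str = "uniform",
                      sigma_range: tuple = (0.05, 0.25),
                      h_range: tuple = (0.5, 1.0),
                      seed: int = 0) -> SyntheticCommunity:
    """Community with Gaussian unimodal species responses on two gradients."""
    if n_sites < 3 or n_species < 1:
        raise ValueError("need n_sites >= 3 and n_species >= 1")
    if not (0 < sigma_range[0] <= sigma_range[1]):
        raise ValueError("invalid sigma_range")
    if not (0 < h_range[0] <= h_range[1] <= 1):
        raise ValueError("invalid h_range")
    env = _environment(n_sites, env_model, stage_rng(seed, "environment"))
    niche_rng = stage_rng(seed, "niche")
    truth = NicheParams(mu=niche_rng.uniform(0.0, 1.0, size=(n_species, 2)),
                        sigma=niche_rng.uniform(*sigma_range, size=(n_species, 2)),
                        h=niche_rng.uniform(*h_range, size=n_species))
    presence = regenerate_presence(truth, env, seed)
    occ = OccurrenceMatrix(_site_ids(n_sites), _species_ids(n_species), presence)
    return SyntheticCommunity(occurrences=occ, environment=env, truth=truth,
                              seed=int(seed), kind="unimodal")


def regenerate_presence(truth, environment, seed: int) -> np.ndarray:
    """Re-draw the presence matrix from (truth, environment, seed).

    Uses the same named random stream as the generators, so the result is
    bit-identical to the original community's presence matrix.
    """
    environment = np.asarray(environment, dtype=float)
    if isinstance(truth, NicheParams):
        pi = occurrence_probabilities(truth, environment)
    else:
        occupancy = np.asarray(truth, dtype=float)
        pi = np.broadcast_to(occupancy[None, :],
                             (environment.shape[0], occupancy.shape[0]))
    rng = stage_rng(seed, "presence")
    return rng.random(pi.shape) < pi


def generate_null(n_sites: int = 300, n_species: int = 150, occupancy=None,
                  seed: int = 0,
                  occupancy_range: tuple = (0.02, 0.30)) -> SyntheticCommunity:
    """Environment-independent null community (negative control).

    Each species j is present at every site independently with probability
    ``occupancy[j]``; when no vector is given, occupancies are drawn from
    U(0.02, 0.30), roughly matching the occupancy spread of the unimodal
    reference communities.  An (unused) environment is still generated so the
    interface matches the unimodal generator.
    """
    if n_sites < 3 or n_species < 1:
        raise ValueError("need n_sites >= 3 and n_species >= 1")
    if occupancy is None:
        occupancy = stage_rng(seed, "occupancy").uniform(*occupancy_range,
                                                         size=n_species)
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (n_species,):
        raise ValueError("occupancy must have one probability per species")
    if np.any((occupancy < 0) | (occupancy > 1)):
        raise ValueError("occupancy probabilities must lie in [0, 1]")
    if np.any(occupancy == 0):
        logger.warning("zero-occupancy species present; they will be dropped "
                       "by clean_matrix")
    env = _environment(n_sites, "uniform", stage_rng(seed, "environment"))
    presence = regenerate_presence(occupancy, env, seed)
    occ = OccurrenceMatrix(_site_ids(n_sites), _species_ids(n_species), presence)
    return SyntheticCommunity(occurrences=occ, environment=env, truth=occupancy,
                              seed=int(seed), kind="null")


def coarsen_to_atlas(c: SyntheticCommunity, cells_per_side: int):
    """Aggregate sites into an atlas-style grid over environmental space.

    Each cell's assemblage is the union of its member sites' assemblages
    (atlas records pool survey effort within a cell).  Empty cells are
    dropped.  Returns (OccurrenceMatrix, cell_centres).
    """
    if cells_per_side < 1:
        raise ValueError("cells_per_side must be >= 1")
    idx = np.clip((c.environment * cells_per_side).astype(int), 0, cells_per_side - 1)
    cells = {}
    for site, (ix, iy) in enumerate(idx):
        cells.setdefault((int(ix), int(iy)), []).append(site)
    keys = sorted(cells)
    presence = np.stack([c.occurrences.presence[cells[k]].any(axis=0) for k in keys])
    ids = [f"cell_{ix}_{iy}" for ix, iy in keys]
    centres = np.array([[(ix + 0.5) / cells_per_side, (iy + 0.5) / cells_per_side]
                        for ix, iy in keys])
    return OccurrenceMatrix(ids, c.occurrences.species_ids, presence), centres


def write_fixture(c: SyntheticCommunity, outdir) -> dict:
    """Write occurrence table (wide), environment table, truth parameters and
    metadata as delimited text / JSON; round-trips through read_fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"occurrences": outdir / "occurrences.tsv",
             "environment": outdir / "environment.tsv",
             "truth": outdir / "truth.tsv",
             "meta": outdir / "meta.json"}
    write_occurrences(c.occurrences, paths["occurrences"])
    env = pd.DataFrame(c.environment, columns=["gradient1", "gradient2"],
                       index=list(c.occurrences.site_ids))
    env.to_csv(paths["environment"], sep="\t", index_label="site",
               float_format="%.17g")
    if c.kind == "unimodal":
        t: NicheParams = c.truth
        truth = pd.DataFrame({"mu1": t.mu[:, 0], "mu2": t.mu[:, 1],
                              "sigma1": t.sigma[:, 0], "sigma2": t.sigma[:, 1],
                              "h": t.h}, index=list(c.occurrences.species_ids))
    else:
        truth = pd.DataFrame({"occupancy": np.asarray(c.truth)},
                             index=list(c.occurrences.species_ids))
    truth.to_csv(paths["truth"], sep="\t", index_label="species",
                 float_format="%.17g")
    paths["meta"].write_text(json.dumps({
        "kind": c.kind, "seed": c.seed,
        "n_sites": c.occurrences.n_sites,
        "n_species": c.occurrences.n_species,
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths


def read_fixture(outdir) -> SyntheticCommunity:
    """Read a fixture written by write_fixture."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text(encoding="utf-8"))
    occ = read_occurrences(outdir / "occurrences.tsv", layout="wide")
    env = pd.read_csv(outdir / "environment.tsv", sep="\t", index_col=0)
    truth_df = pd.read_csv(outdir / "truth.tsv", sep="\t", index_col=0)
    if meta["kind"] == "unimodal":
        truth = NicheParams(mu=truth_df[["mu1", "mu2"]].to_numpy(),
                            sigma=truth_df[["sigma1", "sigma2"]].to_numpy(),
                            h=truth_df["h"].to_numpy())
    else:
        truth = truth_df["occupancy"].to_numpy()
    return SyntheticCommunity(occurrences=occ, environment=env.to_numpy(),
                              truth=truth, seed=int(meta["seed"]),
                              kind=meta["kind"])
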