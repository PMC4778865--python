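"""Site-by-species occurrence data and Jaccard beta diversity.

The universal input of the pipeline is a boolean site x species incidence
matrix (presence/absence).  Beta diversity between two sites i and j is the
Jaccard dissimilarity of their assemblages,

    d_ij = 1 - |A_i & A_j| / |A_i | A_j|,

which is 0 for identical assemblages, 1 for disjoint ones, and a metric on
non-empty assemblages.  Abundance information is deliberately not accepted:
Jaccard is a presence/absence index, and silently binarising counts would hide
a data error.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceMatrix",
    "DissimilarityMatrix",
    "read_occurrences",
    "write_occurrences",
    "clean_matrix",
    "jaccard_dissimilarity",
]

#: tokens that mark the first record of a long-format file as a header line
DEFAULT_HEADER_TOKENS = frozenset({"site", "site_id", "cell", "plot",
                                   "species", "species_id", "taxon"})


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Boolean site x species incidence matrix.

    ``presence[i, j]`` is True when species ``species_ids[j]`` was recorded in
    site ``site_ids[i]``.
    """

    site_ids: tuple
    species_ids: tuple
    presence: np.ndarray

    def __post_init__(self):
        presence = np.asarray(self.presence, dtype=bool)
        object.__setattr__(self, "presence", presence)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        if presence.ndim != 2:
            raise ValueError("presence must be a 2-D matrix")
        if len(self.site_ids) != len(set(self.site_ids)):
            raise ValueError("duplicate site ids")
        if len(self.species_ids) != len(set(self.species_ids)):
            raise ValueError("duplicate species ids")
        if presence.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError(
                f"presence shape {presence.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species")

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    def richness(self) -> np.ndarray:
        """Number of species per site."""
        return self.presence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int),
                            index=list(self.site_ids),
                            columns=list(self.species_ids))


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity between sites, entries in [0, 1]."""

    values: np.ndarray
    site_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        n = len(self.site_ids)
        if values.shape != (n, n):
            raise ValueError("values must be n x n matching site_ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_occurrences(path, layout: str = "wide",
                     header_tokens: Sequence[str] = DEFAULT_HEADER_TOKENS) -> OccurrenceMatrix:
    """Read an occurrence table from delimited text.

    ``wide``: header row of species ids, first column site ids, cells 0/1.
    ``long``: two columns (site, species), one record per occurrence;
    duplicate records collapse to a single presence and a header line is
    skipped when its first field matches one of ``header_tokens``
    (case-insensitive).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty occurrence file")
    delim = _sniff_delimiter(text.splitlines()[0])
    if layout == "wide":
        return _read_wide(text, delim, str(path))
    if layout == "long":
        return _read_long(text, delim, str(path), frozenset(t.lower() for t in header_tokens))
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def _read_wide(text: str, delim: str, name: str) -> OccurrenceMatrix:
    df = pd.read_csv(io.StringIO(text), sep=delim, index_col=0, dtype=str)
    site_ids = [str(s) for s in df.index]
    species_ids = [str(s) for s in df.columns]
    presence = np.zeros(df.shape, dtype=bool)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "0":
                continue
            if cell == "1":
                presence[i, j] = True
            else:
                raise ValueError(
                    f"{name}: cell at site {site_ids[i]!r}, species "
                    f"{species_ids[j]!r} is {cell!r}; expected 0 or 1 "
                    "(abundances are not accepted)")
    return OccurrenceMatrix(site_ids, species_ids, presence)


def _read_long(text: str, delim: str, name: str, header_tokens: frozenset) -> OccurrenceMatrix:
    records = []
    for lineno, row in enumerate(csv.reader(io.StringIO(text), delimiter=delim), start=1):
        if not row or not "".join(row).strip():
            continue
        if len(row) < 2:
            raise ValueError(f"{name}: line {lineno}: expected 2 columns (site, species)")
        site, species = row[0].strip(), row[1].strip()
        if lineno == 1 and site.lower() in header_tokens:
            continue
        records.append((site, species))
    if not records:
        raise ValueError(f"{name}: no occurrence records")
    site_ids = list(dict.fromkeys(s for s, _ in records))
    species_ids = list(dict.fromkeys(sp for _, sp in records))
    site_idx = {s: i for i, s in enumerate(site_ids)}
    sp_idx = {s: j for j, s in enumerate(species_ids)}
    presence = np.zeros((len(site_ids), len(species_ids)), dtype=bool)
    for site, species in records:
        presence[site_idx[site], sp_idx[species]] = True
    return OccurrenceMatrix(site_ids, species_ids, presence)


def write_occurrences(m: OccurrenceMatrix, path, sep: str = "\t") -> None:
    """Write a wide-layout occurrence table (round-trips through read_occurrences)."""
    m.to_frame().to_csv(path, sep=sep, index_label="site")


def clean_matrix(m: OccurrenceMatrix, min_sites: int = 3) -> OccurrenceMatrix:
    """Drop empty sites (all-zero rows) and unobserved species (all-zero columns).

    Order of the remaining ids is preserved and removals are logged.  Raises
    if fewer than ``min_sites`` sites or no species remain, since an
    ordination is then impossible.
    """
    row_keep = m.presence.any(axis=1)
    col_keep = m.presence.any(axis=0)
    if (~row_keep).any():
        dropped = [m.site_ids[i] for i in np.flatnonzero(~row_keep)]
        logger.warning("clean_matrix: dropping %d empty site(s): %s",
                       len(dropped), ", ".join(map(str, dropped[:10])))
    if (~col_keep).any():
        dropped = [m.species_ids[j] for j in np.flatnonzero(~col_keep)]
        logger.warning("clean_matrix: dropping %d unobserved species", len(dropped))
    if row_keep.all() and col_keep.all():
        return m
    out = OccurrenceMatrix(
        [s for s, k in zip(m.site_ids, row_keep) if k],
        [s for s, k in zip(m.species_ids, col_keep) if k],
        m.presence[np.ix_(row_keep, col_keep)],
    )
    if out.n_sites < min_sites:
        raise ValueError(f"only {out.n_sites} non-empty sites remain; "
                         f"need at least {min_sites} for ordination")
    if out.n_species < 1:
        raise ValueError("no species remain after cleaning")
    return out


def jaccard_dissimilarity(m: OccurrenceMatrix) -> DissimilarityMatrix:
    """Pairwise Jaccard dissimilarity (1 minus Jaccard similarity) between sites."""
    if not m.presence.any(axis=1).all():
        raise ValueError("matrix contains empty sites; run clean_matrix first")
    condensed = pdist(m.presence, metric="jaccard")
    return DissimilarityMatrix(squareform(condensed), m.site_ids)
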