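"""Deterministic seed derivation.

Every stage of the pipeline draws its randomness from a child stream of a
single master seed.  Children are derived from ``(master_seed, crc32(label))``
so that a stage can be re-run in isolation and reproduce exactly what it did
inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed_sequence", "stage_rng"]


def stage_seed_sequence(master_seed: int, label: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage, derived from the master seed."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                   zlib.crc32(label.encode("utf-8"))])


def stage_rng(master_seed: int, label: str) -> np.random.Generator:
    """Generator for a named stage, derived from the master seed."""
    return np.random.Generator(np.random.PCG64(stage_seed_sequence(master_seed, label)))
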