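"""Shared numerical helpers and seeded RNG substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["soft_threshold", "substream", "as_rng"]


def soft_threshold(z: float, lam: float) -> float:
    """Proximal operator of lam*|.| evaluated at z."""
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from a master seed.

    The stream depends only on (seed, name, index), so adding new streams
    elsewhere never perturbs existing ones.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()), index))
    return np.random.default_rng(ss)


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
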