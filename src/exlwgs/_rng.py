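"""Deterministic seed plumbing.

Every stochastic operation takes either an integer seed or a Generator.
Stage seeds are derived from a single master seed plus a stage name, so a
pipeline re-run stage-by-stage from persisted intermediates reproduces a
single-process run bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from a master seed and a stage name."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded deterministically by (master seed, stage name)."""
    return np.random.default_rng(derive_seed(master_seed, stage))


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
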