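"""Seed-derivation helpers.

Every stochastic operation takes one integer seed and derives an independent
stream from it via :class:`numpy.random.SeedSequence` spawn keys, so composed
pipelines stay reproducible without sharing generator state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from", "child_seeds"]


def rng_from(seed: int, *key: int) -> np.random.Generator:
    """Return a generator for ``seed`` with an optional spawn key.

    Distinct keys give statistically independent streams for the same seed.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from one seed."""
    rng = rng_from(seed, 0xC11D)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
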