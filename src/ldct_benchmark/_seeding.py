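"""Deterministic seed derivation.

All randomness in the package flows from a single integer seed. Stage seeds
are derived with :class:`numpy.random.SeedSequence` so that independent
stages (phantom geometry, high-dose noise, low-dose noise, optimizer, ...)
receive statistically independent streams while the whole pipeline remains
reproducible from one number.
"""

from __future__ import annotations

import numpy as np

# keep derived integer seeds below 2**31 so they survive round trips through
# JSON configs and external tools that expect C `int`
_SEED_MOD = 2**31


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from a single root seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % _SEED_MOD for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed: int, *path: int) -> np.random.Generator:
    """A generator seeded by ``seed`` and an optional integer path.

    ``rng_from(seed, a, b)`` and ``rng_from(seed, a, c)`` are independent
    streams for ``b != c``; the same path always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path)))
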