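"""Uniform handling of seeds: int | SeedSequence | Generator | None."""

from __future__ import annotations

import numpy as np

__all__ = ["as_generator", "spawn_generators", "as_int_seed"]


def as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_generators(seed, n: int) -> list[np.random.Generator]:
    """n independent child generators, deterministic in the parent seed."""
    if isinstance(seed, np.random.Generator):
        return seed.spawn(n)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def as_int_seed(seed) -> int | None:
    """A 31-bit int for APIs that only take integer random states."""
    if seed is None:
        return None
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2**31))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return int(ss.generate_state(1)[0] % 2**31)
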