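"""Shared helpers: seeded RNG hierarchy and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "as_rng"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def stage_rng(seed: int, *names: str) -> np.random.Generator:
    """Derive a generator for a named (sub)stage from one global seed.

    The same (seed, names) always yields the same stream, and distinct
    stage names yield independent streams, so partial pipeline re-runs
    reproduce downstream results bit-exactly.
    """
    ss = np.random.SeedSequence([int(seed) % (2**31)] + [_name_key(n) for n in names])
    return np.random.default_rng(ss)


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
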