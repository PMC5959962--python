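"""Deterministic seed derivation shared by all stages.

Every source of randomness in the package flows through one master seed.
Stage- and iteration-level generators are derived with a stable hash of the
context (stage name, iteration index, filter, size), so re-running any single
iteration reproduces it exactly and no two stages share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _token(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(repr(part).encode("utf-8"))


def derive_seed(master_seed: int, *context: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and context tokens."""
    ss = np.random.SeedSequence([int(master_seed)] + [_token(p) for p in context])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master_seed: int, *context: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from (master_seed, context)."""
    ss = np.random.SeedSequence([int(master_seed)] + [_token(p) for p in context])
    return np.random.default_rng(ss)
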