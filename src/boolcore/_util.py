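"""Small shared helpers: seeding and stable hashing."""

from __future__ import annotations

import zlib

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stable_u32(text: str) -> int:
    """Process-independent 32-bit hash of a string (CRC32)."""
    return zlib.crc32(text.encode("utf-8")) & 0xFFFFFFFF
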