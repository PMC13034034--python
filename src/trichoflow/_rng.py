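"""Seed-substream management.

All randomness in the pipeline flows from a single integer seed. Each stage
draws from a named substream derived from that seed, so re-ordering or
skipping stages never perturbs another stage's random numbers.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_int"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from the global seed.

    The stage name is hashed with CRC32 (stable across processes, unlike
    the builtin ``hash``) and mixed into a SeedSequence with the seed.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def substream_int(seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
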