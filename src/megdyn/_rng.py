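"""Seed management.

All randomness in the package flows from a single integer seed through a
counter-based generator (Philox) split by named streams, so that every
module is independently reproducible: the same (seed, stream key) pair
always yields the same draws regardless of what other modules consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng"]


def _key_to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def split_rng(seed: int, *stream_key) -> np.random.Generator:
    """Return a Generator for the given seed and stream key.

    Parameters
    ----------
    seed : int
        Master seed (non-negative, below 2**31 in practice).
    *stream_key : int or str
        Identifiers naming the consumer; strings are hashed (CRC32).
    """
    spawn = tuple(_key_to_int(k) for k in stream_key)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn)
    return np.random.Generator(np.random.Philox(ss))
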