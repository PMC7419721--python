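"""Deterministic random-stream derivation.

Every source of randomness in the package is a :class:`numpy.random.Generator`
derived from a single root seed plus a tuple of stream labels, so any stage
(cohort draw, one session, one trial sequence) can be replayed independently.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf8")) & 0x7FFFFFFF


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    Labels may be strings (stage names) or integers (indices); they are mapped
    to a :class:`numpy.random.SeedSequence` spawn key, so distinct label tuples
    give statistically independent streams and identical tuples replay exactly.
    """
    spawn = tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=spawn))
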