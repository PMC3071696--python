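"""Deterministic seed fan-out.

One global integer seed is turned into independent per-stage streams via
named SeedSequence spawning, so every random draw in a run is traceable to
the global seed and stages stay reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so the mapping is stable across
    runs and platforms and independent of call order.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def subseed(seed: int, name: str) -> int:
    """A derived 31-bit integer seed for the named substream."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
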