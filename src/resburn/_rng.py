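"""Seeded sub-stream management.

A single top-level seed governs every stochastic stage. Each stage pulls an
independent, reproducible generator keyed by a stable stream name, so stages
can be re-run in isolation without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named sub-stream of ``seed``.

    The stream key is derived from a CRC32 of the name, so the mapping is
    stable across processes and Python versions (unlike ``hash``).
    """
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])
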