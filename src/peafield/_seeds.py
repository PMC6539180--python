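"""Deterministic named RNG sub-streams.

All randomness in the package flows from one top-level integer seed; each
operation draws from a sub-stream keyed by a stable name, so adding or
reordering one operation never perturbs another's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the sub-stream ``name`` of top-level ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
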