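"""Named, independent RNG streams derived from one session seed.

Each consumer (deviant placement, agent behaviour, latency noise, ...)
gets its own stream keyed by name, so adding a consumer never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the (seed, name) stream; stable across sessions/platforms."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
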