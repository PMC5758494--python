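"""Named, independent random-number streams derived from a single seed.

Every stochastic sub-process draws from its own stream so that adding a new
generator (or reordering calls) never perturbs the output of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for stream ``name`` under the run-level ``seed``.

    The stream key is a CRC32 of the name, so the mapping is stable across
    sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
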