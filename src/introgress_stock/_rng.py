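"""Seeded random-number substreams.

All randomness in the package flows from one top-level integer seed.  Each
consumer asks for a named substream, so regenerating one part of a study
(e.g. the run-year samples) never perturbs another part generated from the
same seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC32 of the name, so it is stable
    across sessions and platforms.
    """
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
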