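"""Seeded random-number substreams.

All randomness in the pipeline flows from a single top-level integer seed.
Each stage draws from a named substream so that adding draws to one stage
never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from the top-level seed.

    The stream key is a CRC32 of the stage name, so the mapping is stable
    across platforms and Python hash randomisation.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
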