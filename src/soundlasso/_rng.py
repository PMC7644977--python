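"""Named, reproducible random substreams.

A dataset is generated from one master seed, but each logical source of
randomness (cluster structure, each predictor, the noise terms) draws from
its own substream keyed by name.  Adding or removing a predictor therefore
never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under `seed`.

    The substream key is a CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
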