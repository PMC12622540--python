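"""Named random substreams derived from one master seed.

Every stochastic stage of the pipeline draws from its own substream so that
re-running a single stage with the same master seed reproduces it exactly,
independent of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of ``name``, so stream identity is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))
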