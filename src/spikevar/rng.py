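"""Named random substreams derived from a single session seed.

Every source of randomness in the package (stimulus draws, ground-truth
draws, Poisson spiking, fold shuffles, shuffle surrogates) pulls its
generator from here, so one config seed reproduces a whole run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC of the name, so streams are stable across runs
    and independent across names.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
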