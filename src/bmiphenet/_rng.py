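"""Named, reproducible random substreams.

Every stochastic stage draws from its own substream derived from one master
seed, so changing e.g. the phecode panel never perturbs the genotype draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """A 31-bit integer seed for the named substream (for libraries that
    take plain integer seeds, e.g. networkx)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A numpy Generator for the named substream of ``seed``.

    Deterministic: the same (seed, name) pair always yields an identical
    stream, independently of any other substream drawn from the same seed.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return np.random.default_rng(ss)
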