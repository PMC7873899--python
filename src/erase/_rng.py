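"""Named random substreams derived from one master seed.

Every source of randomness in the package draws from a substream obtained by
combining the master seed with a stable CRC32 hash of a name (and optional
integer tags, e.g. a replicate index).  Substreams are statistically
independent, so two pipelines with different seeds, or two stages with
different names, never interact through hidden RNG state.
"""

from __future__ import annotations

import zlib

import numpy as np

_MAX31 = 2**31 - 1


def substream(seed: int, name: str, *tags: int) -> np.random.Generator:
    """Return a Generator for substream ``name`` (+ integer tags) of ``seed``."""
    key = [int(seed) & _MAX31, zlib.crc32(name.encode()) & _MAX31]
    key.extend(int(t) & _MAX31 for t in tags)
    return np.random.default_rng(np.random.SeedSequence(key))


def derive_int_seed(seed: int, name: str, *tags: int) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    return int(substream(seed, name, *tags).integers(_MAX31))
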