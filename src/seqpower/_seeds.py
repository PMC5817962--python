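"""Counter-based seed derivation.

Every stochastic stage receives a generator derived from the run's master seed
plus a structured key (stage tag and counter indices).  Keys map to a
``numpy.random.SeedSequence`` spawn key, so cells of a grid can be computed in
any order — or in parallel — with identical results and no global RNG state.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_part(part) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("seed key parts must be non-negative")
        return int(part)
    raise TypeError(f"seed key parts must be int or str, got {type(part)!r}")


def derive_rng(master_seed: int, *key) -> np.random.Generator:
    """A fresh generator for (master_seed, key...); deterministic and stateless."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(_key_part(k) for k in key))
    return np.random.default_rng(ss)
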