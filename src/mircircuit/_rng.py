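"""Stable keyed seed derivation.

One global seed drives every stage; per-stage generators are derived by
hashing (seed, key) so that changing one stage's consumption (e.g. the
number of permutations) never perturbs another stage's random stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, key: str) -> int:
    """Derive a stable 31-bit child seed from a parent seed and a string key."""
    digest = hashlib.sha256(f"{int(seed)}:{key}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, key: str) -> np.random.Generator:
    """A numpy Generator keyed to (seed, key)."""
    return np.random.default_rng(child_seed(seed, key))
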