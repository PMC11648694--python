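"""Shared helpers: seed derivation and RNG plumbing."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int | None, *names: object) -> int | None:
    """Derive a stable child seed from a master seed and a label path.

    Hash-based so that adding a new consumer never perturbs the stream any
    existing consumer sees.  Returns None if master is None (fresh entropy).
    """
    if master is None:
        return None
    h = hashlib.sha256(("/".join(str(n) for n in (master, *names))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
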