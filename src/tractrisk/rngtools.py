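"""Deterministic seed derivation.

Every stochastic stage derives its own substream seed from the master seed,
a stage label, and (for tract-parallel work) the tract id, so per-tract
results are independent of execution order and of which other stages ran.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *parts) -> int:
    """Stable 31-bit seed from a master seed plus string/int labels."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for p in parts:
        h.update(b"\x1f")
        h.update(str(p).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *parts))
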