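"""Stable per-entity random substreams.

Every stochastic stage derives an independent child seed from the master
seed and a tuple of string labels (site, year, iteration, ...) by hashing.
This keeps runs bit-reproducible regardless of iteration order and lets
any single (site, year, iteration) soundscape be rebuilt in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master_seed: int, *labels: object) -> int:
    """Derive a deterministic 63-bit child seed from labels."""
    key = f"{int(master_seed)}|" + "|".join(str(x) for x in labels)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


def child_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """A fresh generator on the substream identified by ``labels``."""
    return np.random.default_rng(child_seed(master_seed, *labels))
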