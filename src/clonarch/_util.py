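"""Shared numeric helpers: stable sub-stream seeding and half-up rounding."""

from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for a named sub-stream of the master seed.

    The sub-stream is derived by stable (SHA-256) hashing of the key tuple,
    so adding zones, loci or wells never perturbs the draws of existing ones,
    and the mapping is identical across platforms and Python processes.
    """
    digest = hashlib.sha256(repr(keys).encode("utf-8")).digest()
    entropy = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), entropy]))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (school rounding), e.g. 0.25 -> 0.3 at 1 digit."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
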