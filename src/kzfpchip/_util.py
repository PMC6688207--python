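"""Small shared helpers: half-up rounding and stable sub-seeding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed summary tables do.

    Python's built-in ``round`` is banker's rounding; percentage tables in the
    literature round 0.05 up, so 51.85 -> 51.9 rather than 51.8.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sub_rng(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for component *name*, stably derived from *seed*.

    Each output of the simulator draws from its own stream so that adding a new
    output never perturbs existing ones.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(tag,)))
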