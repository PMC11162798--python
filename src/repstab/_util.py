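"""Shared numeric helpers: commercial rounding and seed management."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["round_half_up", "round_half_away_int", "child_seeds"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero (commercial rounding).

    Python's builtin ``round`` uses banker's rounding; reported repeat
    lengths, percentages and ratios here always round ties away from zero.
    """
    if not np.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_away_int(x: float) -> int:
    """Nearest integer, ties away from zero."""
    return int(round_half_up(x, 0))


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one top-level seed.

    Uses :class:`numpy.random.SeedSequence` spawning so that per-operation
    streams are statistically independent and reproducible.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)) for child in ss.spawn(n)]
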