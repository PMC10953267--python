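"""Small shared helpers: reporting-grade rounding and seed derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_away", "derive_seed", "rng_from"]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Plain ``round`` rounds half to even (0.445 -> 0.44); printed psychometric
    tables round half away from zero (0.445 -> 0.45).  Decimal arithmetic on
    the shortest repr avoids binary-float artefacts.
    """
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(master: int, *keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from a master seed.

    Used so that every stochastic sub-stage (bootstrap replicate, CV fold
    shuffle) gets an independent but reproducible stream.
    """
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(master: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *[int(k) for k in keys]]))
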