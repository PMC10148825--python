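"""Half-up decimal rounding for table reproduction.

Published MCDM tables are typically produced in spreadsheets, which round
half away from zero on the decimal representation — not banker's rounding,
and not binary-float rounding. ``round_half_up`` reproduces that behaviour.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_up", "round_half_up_array"]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    A pre-quantization guard at ``ndigits + 6`` decimals absorbs binary
    floating-point noise, so a value that is an exact decimal tie in real
    arithmetic (e.g. 0.45 + 0.35*0.75 = 0.7125) rounds up even when the
    float representation falls a few ulp below the tie.
    """
    if not np.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    guard = Decimal(1).scaleb(-(ndigits + 6))
    d = d.quantize(guard, rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def round_half_up_array(a: np.ndarray, ndigits: int = 3) -> np.ndarray:
    """Elementwise :func:`round_half_up`; NaN entries pass through."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    flat_in, flat_out = a.ravel(), out.ravel()
    for i, v in enumerate(flat_in):
        flat_out[i] = round_half_up(v, ndigits)
    return out
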