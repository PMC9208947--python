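"""Centralized parity-constrained rounding rules.

The adaptive attention-kernel formula needs a nearest-*odd* integer and the
channel-selection formula a nearest-*even* integer.  Half-way ties are not
defined by the formulas themselves, so the conventions live here, in one
place: odd rounding resolves ties downward, even rounding upward.
"""

import math


def nearest_odd(t: float, minimum: int = 1) -> int:
    """Nearest odd integer to ``t``; exact half-way ties go to the lower odd."""
    lo = 2 * math.floor((t - 1.0) / 2.0) + 1  # greatest odd <= t
    hi = lo + 2
    k = lo if (t - lo) <= (hi - t) else hi
    return max(k, minimum)


def nearest_even(t: float) -> int:
    """Nearest even integer to ``t``; exact half-way ties go to the upper even."""
    lo = 2 * math.floor(t / 2.0)  # greatest even <= t
    hi = lo + 2
    return lo if (t - lo) < (hi - t) else hi
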