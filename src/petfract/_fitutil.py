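"""Shared least-squares helper for log-log scaling fits.

Both the box-counting dimension and every generalized-dimension moment are
slopes of straight-line fits in log-log coordinates; routing them all through
one routine keeps the occupancy exponent (q = 0 moment) bit-identical between
the two modules.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r2: float
    stderr: float


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares of y against x.

    A constant response is a perfect fit to a horizontal line, so r2 is
    reported as 1 with zero slope and zero standard error (scipy would
    return NaN for the degenerate correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least two points for a linear fit")
    if np.ptp(y) == 0.0:
        return LinearFit(0.0, float(y[0]), 1.0, 0.0)
    res = stats.linregress(x, y)
    return LinearFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue) ** 2,
        float(res.stderr),
    )
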