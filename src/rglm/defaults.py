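"""Default-parameter rules for the number of features sampled per bag.

The fraction of features drawn into each bag depends on the *effective*
feature count N*: the original features plus all interaction terms of distinct
features up to the chosen order.  Small problems (N* <= 10) use every feature;
large ones (N* > 300) use 20%; in between the fraction follows the line
through (10, 1) and (300, 0.2), whose printed coefficients are
``1.0276 - 0.00276 * N*``.
"""

from __future__ import annotations

import math
from math import comb

__all__ = [
    "effective_feature_count",
    "default_fraction",
    "resolve_n_features_in_bag",
    "interpolation_line",
    "INTERCEPT",
    "SLOPE",
]

# stored exactly as printed so resolved defaults match the published table
INTERCEPT = 1.0276
SLOPE = -0.00276
_N_STAR_LOW = 10
_N_STAR_HIGH = 300
_FRACTION_HIGH = 0.2


def effective_feature_count(n_features: int, order: int) -> int:
    """Effective feature count N*: distinct-feature terms of size 1..order.

    order 1 -> N;  order 2 -> N + N(N-1)/2;  order 3 -> (N^3 + 5N)/6.
    """
    N = int(n_features)
    if N < 1:
        raise ValueError("n_features must be >= 1")
    if order not in (1, 2, 3):
        raise ValueError("interaction order must be 1, 2 or 3")
    return sum(comb(N, j) for j in range(1, order + 1))


def default_fraction(n_star: int) -> float:
    """Default nFeaturesInBag / N as a function of the effective count N*."""
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    if n_star <= _N_STAR_LOW:
        return 1.0
    if n_star <= _N_STAR_HIGH:
        return INTERCEPT + SLOPE * n_star
    return _FRACTION_HIGH


def resolve_n_features_in_bag(n_features: int, order: int) -> int:
    """Resolved default for the per-bag subspace size.

    ``round(fraction * N)`` with half-up rounding, clamped to [1, N].
    """
    N = int(n_features)
    frac = default_fraction(effective_feature_count(N, order))
    return int(min(max(math.floor(frac * N + 0.5), 1), N))


def interpolation_line(
    p1: "tuple[float, float]", p2: "tuple[float, float]"
) -> "tuple[float, float]":
    """Exact (intercept, slope) of the line through two points."""
    (x1, y1), (x2, y2) = p1, p2
    if x1 == x2:
        raise ValueError("points must have distinct x values")
    slope = (y2 - y1) / (x2 - x1)
    return y1 - slope * x1, slope
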