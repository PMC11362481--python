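"""Conversions between construct reliability and common factor loadings.

When planning a simulation, plausible loading values can be read off
published reliability figures.  With identical standardized loadings λ
across k items, the composite (construct) reliability is

    α = (k λ)² / ((k λ)² + k (1 − λ²)) ,

and solving for λ gives

    λ = √( α / (α + k − α·k) ) .

For a single test with a reported test–retest correlation r, the loading is
simply λ = √r (the correlation of two parallel administrations is the
squared loading on the common factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "ReliabilitySpec",
    "loading_from_reliability",
    "reliability_from_loading",
    "loading_from_test_retest",
]


@dataclass(frozen=True)
class ReliabilitySpec:
    """A (reliability, item count, loading) triple satisfying the identity."""

    alpha: float
    k: int
    lam: float

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.lam < 1.0:
            raise InvalidParameterError(f"lam must lie in (0, 1), got {self.lam}")
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")


def _check_k(k: int) -> None:
    if k < 1:
        raise InvalidParameterError(f"item count k must be >= 1, got {k}")


def loading_from_reliability(alpha: float, k: int) -> float:
    """Common loading implied by construct reliability α from k items."""
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    _check_k(k)
    den = alpha + k - alpha * k
    if den <= 0.0:
        raise InvalidParameterError(f"alpha + k - alpha*k = {den} must be positive")
    return math.sqrt(alpha / den)


def reliability_from_loading(lam: float, k: int) -> float:
    """Composite reliability of k items with common loading λ.

    Exact inverse of :func:`loading_from_reliability`.
    """
    if not 0.0 < lam < 1.0:
        raise InvalidParameterError(f"lam must lie in (0, 1), got {lam}")
    _check_k(k)
    num = (k * lam) ** 2
    return num / (num + k * (1.0 - lam * lam))


def loading_from_test_retest(r: float) -> float:
    """Loading √r implied by a test–retest correlation r of a single test."""
    if not 0.0 < r <= 1.0:
        raise InvalidParameterError(f"test-retest correlation must lie in (0, 1], got {r}")
    return math.sqrt(r)
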