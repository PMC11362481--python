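"""CFI, RMSEA and BIC — the three indices driving model selection.

Formulas are the standard normal-theory ones, with the sample-size
multiplier convention fixed in :mod:`sempower.ml_estimator` (T = n·F by
default).  CFI compares the candidate against the independence baseline,
RMSEA measures misfit per degree of freedom, and BIC = −2ℓ + q·ln n ranks
candidates that pass the absolute-fit cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError
from .ml_estimator import FitResult, fit_baseline

__all__ = ["FitIndices", "cfi", "rmsea", "bic", "compute_indices"]


@dataclass(frozen=True)
class FitIndices:
    """Selection-relevant indices for one candidate model on one dataset."""

    model_id: int
    cfi: float
    rmsea: float
    bic: float


def cfi(T: float, df: float, T0: float, df0: float) -> float:
    """Comparative fit index 1 − max(T−df, 0)/max(T−df, T0−df0, 0).

    Returns 1.0 when numerator and denominator are both zero (candidate and
    baseline each fit no worse than their degrees of freedom).
    """
    if df0 < df:
        raise InvalidParameterError("baseline df must be >= model df")
    num = max(T - df, 0.0)
    den = max(T - df, T0 - df0, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def rmsea(T: float, df: float, n: int) -> float:
    """Root mean square error of approximation √(max(T−df,0)/(df·n))."""
    if df <= 0:
        raise InvalidParameterError("RMSEA is undefined for df = 0 (just-identified)")
    return math.sqrt(max(T - df, 0.0) / (df * n))


def bic(loglik: float, q: int, n: int) -> float:
    """Bayesian information criterion −2ℓ + q·ln n (lower is better)."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    return -2.0 * loglik + q * math.log(n)


def compute_indices(fit: FitResult, baseline: FitResult, model_id: int) -> FitIndices:
    """Bundle CFI/RMSEA/BIC for a converged fit against its baseline."""
    return FitIndices(
        model_id=model_id,
        cfi=cfi(fit.T, fit.df, baseline.T, baseline.df),
        rmsea=rmsea(fit.T, fit.df, fit.n),
        bic=bic(fit.loglik, fit.q, fit.n),
    )
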