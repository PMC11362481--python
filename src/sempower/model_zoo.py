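"""Confirmatory factor models for the memory-structure model comparison.

A :class:`ModelSpec` holds a loading matrix Λ (p indicators × m factors), a
factor covariance matrix Φ and a vector of residual variances Θ, each entry
either fixed at a numeric value or free (with a starting value).  A fully
numeric spec is a population model that implies the covariance matrix

    Σ = Λ Φ Λ' + Θ .

Three candidate structures for 13 memory tasks are provided:

* :func:`build_unitary` — one general memory factor (Model 1),
* :func:`build_bipartite` — episodic vs. semantic memory (Model 2),
* :func:`build_tripartite` — pattern separation / pattern completion /
  generalization (Model 3), with tasks 5 and 6 cross-loading on the first
  two factors.

All constructors standardize the indicators: loadings are ``a`` (rescaled to
``b = a/sqrt(2 + 2 r)`` for the cross-loading tasks) and residual variances
are ``1 - a**2``, so every implied indicator variance equals one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegeneracyError,
    InvalidParameterError,
    ModelSyntaxError,
    UnderIdentifiedError,
)

__all__ = [
    "ModelSpec",
    "ImpliedCovariance",
    "TASKS",
    "cross_loading_scale",
    "build_unitary",
    "build_bipartite",
    "build_tripartite",
    "free_pattern",
    "implied_covariance",
    "count_free_parameters",
    "model_df",
    "parse_model",
    "to_model_string",
]

#: The 13 manifest memory-task indicators used throughout.
TASKS: tuple[str, ...] = tuple(f"task{i}" for i in range(1, 14))

VARIANCE_STANDARDIZED = "variance_standardized"
MARKER = "marker"


@dataclass(frozen=True)
class ModelSpec:
    """A confirmatory factor model, population or fitted-pattern.

    Entry conventions: an entry is a *path* of the model whenever its free
    mask is True or its value is nonzero; loadings that are fixed at zero
    with ``free=False`` are structural zeros.  Free entries carry their
    starting value in the value array.
    """

    name: str
    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: np.ndarray          # p × m values (fixed value or start)
    loadings_free: np.ndarray     # p × m bool
    factor_cov: np.ndarray        # m × m values, symmetric
    factor_cov_free: np.ndarray   # m × m bool, symmetric
    residuals: np.ndarray         # p values
    residuals_free: np.ndarray    # p bool
    identification: str = VARIANCE_STANDARDIZED

    def __post_init__(self):
        p, m = len(self.indicators), len(self.factors)
        for attr, shape in (
            ("loadings", (p, m)),
            ("loadings_free", (p, m)),
            ("factor_cov", (m, m)),
            ("factor_cov_free", (m, m)),
            ("residuals", (p,)),
            ("residuals_free", (p,)),
        ):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != shape:
                raise InvalidParameterError(
                    f"{self.name}: {attr} has shape {arr.shape}, expected {shape}"
                )
            object.__setattr__(self, attr, arr.copy())
        self.loadings.setflags(write=False)
        self.factor_cov.setflags(write=False)
        self.residuals.setflags(write=False)
        if not np.allclose(self.factor_cov, self.factor_cov.T):
            raise InvalidParameterError(f"{self.name}: factor_cov is not symmetric")
        if not np.array_equal(self.factor_cov_free, self.factor_cov_free.T):
            raise InvalidParameterError(f"{self.name}: factor_cov_free is not symmetric")
        pattern = self.loadings_free | (self.loadings != 0.0)
        if not pattern.any(axis=1).all():
            missing = [t for t, ok in zip(self.indicators, pattern.any(axis=1)) if not ok]
            raise InvalidParameterError(
                f"{self.name}: indicators without any loading: {missing}"
            )
        if not pattern.any(axis=0).all():
            empty = [f for f, ok in zip(self.factors, pattern.any(axis=0)) if not ok]
            raise InvalidParameterError(f"{self.name}: factors without indicators: {empty}")
        if self.identification not in (VARIANCE_STANDARDIZED, MARKER):
            raise InvalidParameterError(
                f"{self.name}: unknown identification {self.identification!r}"
            )

    # -- basic queries ---------------------------------------------------
    @property
    def p(self) -> int:
        """Number of manifest indicators."""
        return len(self.indicators)

    @property
    def m(self) -> int:
        """Number of latent factors."""
        return len(self.factors)

    @property
    def is_numeric(self) -> bool:
        """True when the spec has no free entries (a population model)."""
        return not (
            self.loadings_free.any()
            or self.factor_cov_free.any()
            or self.residuals_free.any()
        )

    @property
    def loading_pattern(self) -> np.ndarray:
        """Boolean p × m matrix of paths (free or fixed-nonzero loadings)."""
        return self.loadings_free | (self.loadings != 0.0)


@dataclass(frozen=True)
class ImpliedCovariance:
    """Model-implied covariance matrix Σ = ΛΦΛ' + Θ of a population model."""

    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        self.sigma.setflags(write=False)


def cross_loading_scale(a: float, cov1: float) -> float:
    """Rescaled loading ``b = a / sqrt(2 + 2*cov1)`` for a double-loading task.

    A task loading with equal strength ``b`` on two factors with covariance
    ``cov1`` contributes ``b**2 * (2 + 2*cov1)`` to its model-implied
    variance; this choice of ``b`` makes that contribution equal ``a**2``,
    so the standardized residual ``1 - a**2`` keeps the total variance at 1.
    """
    if cov1 <= -1.0:
        raise InvalidParameterError(f"cov1 must exceed -1, got {cov1}")
    return a / math.sqrt(2.0 + 2.0 * cov1)


def _check_loading(a: float) -> None:
    if not 0.0 < a < 1.0:
        raise InvalidParameterError(f"loading a must lie in (0, 1), got {a}")


def _check_corr(r: float) -> None:
    if not -1.0 < r <= 1.0:
        raise InvalidParameterError(f"factor correlation must lie in (-1, 1], got {r}")


def _population(name, factors, allocation, a, phi, cross=()):
    """Assemble a standardized numeric spec from a factor→tasks allocation."""
    p, m = len(TASKS), len(factors)
    idx = {t: i for i, t in enumerate(TASKS)}
    lam = np.zeros((p, m))
    for j, tasks in enumerate(allocation):
        for t in tasks:
            lam[idx[t], j] = a
    for t, value in cross:
        lam[idx[t], :] = 0.0
        lam[idx[t], [j for j, tasks in enumerate(allocation) if t in tasks]] = value
    return ModelSpec(
        name=name,
        indicators=TASKS,
        factors=tuple(factors),
        loadings=lam,
        loadings_free=np.zeros((p, m), dtype=bool),
        factor_cov=phi,
        factor_cov_free=np.zeros((m, m), dtype=bool),
        residuals=np.full(p, 1.0 - a * a),
        residuals_free=np.zeros(p, dtype=bool),
    )


def build_unitary(a: float) -> ModelSpec:
    """Population Model 1: a single g-factor of memory for all 13 tasks."""
    _check_loading(a)
    return _population("unitary", ("g",), (TASKS,), a, np.eye(1))


#: Default Model 2 allocation: Task 10 sits with the episodic tasks.
BIPARTITE_ALLOCATION: tuple[tuple[str, ...], tuple[str, ...]] = (
    TASKS[0:10],
    TASKS[10:13],
)


def build_bipartite(
    a: float,
    r: float,
    allocation: tuple[Sequence[str], Sequence[str]] | None = None,
) -> ModelSpec:
    """Population Model 2: episodic and semantic factors with correlation r.

    The default allocation puts tasks 1–10 on the episodic factor and tasks
    11–13 on the semantic factor; pass ``allocation`` to override.
    """
    _check_loading(a)
    _check_corr(r)
    if allocation is None:
        allocation = BIPARTITE_ALLOCATION
    phi = np.array([[1.0, r], [r, 1.0]])
    return _population("bipartite", ("episodic", "semantic"), allocation, a, phi)


TRIPARTITE_ALLOCATION: tuple[tuple[str, ...], ...] = (
    TASKS[0:6],    # pattern separation: tasks 1-6
    TASKS[4:9],    # pattern completion: tasks 5-9 (5 and 6 cross-load)
    TASKS[9:13],   # generalization: tasks 10-13
)


def build_tripartite(a: float, r: float) -> ModelSpec:
    """Population Model 3: pattern separation / completion / generalization.

    All three pairwise factor correlations are set to ``r``.  Tasks 5 and 6
    load on both ps and pc with the rescaled value
    ``b = a / sqrt(2 + 2 r)`` so that their total variance stays 1.
    """
    _check_loading(a)
    _check_corr(r)
    b = cross_loading_scale(a, r)
    phi = np.full((3, 3), r)
    np.fill_diagonal(phi, 1.0)
    cross = (("task5", b), ("task6", b))
    return _population(
        "tripartite", ("ps", "pc", "gen"), TRIPARTITE_ALLOCATION, a, phi, cross
    )


def free_pattern(
    spec: ModelSpec,
    identification: str = VARIANCE_STANDARDIZED,
    loading_start: float = 0.5,
    residual_start: float = 0.5,
) -> ModelSpec:
    """Turn a spec into a fitted pattern: free every path, keep structure.

    Under ``variance_standardized`` identification the factor variances stay
    fixed at 1 and all loadings are free; under ``marker`` the first
    indicator loading uniquely on each factor (falling back to the first
    loading) is fixed at 1 and the factor variances are freed.  Off-diagonal
    factor covariances and all residual variances are free in both modes.
    """
    pattern = spec.loading_pattern
    p, m = pattern.shape
    loadings = np.where(pattern, loading_start, 0.0)
    loadings_free = pattern.copy()
    phi = np.eye(m)
    phi_free = ~np.eye(m, dtype=bool)
    if identification == MARKER:
        for j in range(m):
            rows = np.flatnonzero(pattern[:, j])
            unique = [i for i in rows if pattern[i].sum() == 1]
            marker = unique[0] if unique else rows[0]
            loadings[marker, j] = 1.0
            loadings_free[marker, j] = False
        phi_free |= np.eye(m, dtype=bool)
        np.fill_diagonal(phi, residual_start)
    elif identification != VARIANCE_STANDARDIZED:
        raise InvalidParameterError(f"unknown identification {identification!r}")
    return ModelSpec(
        name=spec.name,
        indicators=spec.indicators,
        factors=spec.factors,
        loadings=loadings,
        loadings_free=loadings_free,
        factor_cov=phi,
        factor_cov_free=phi_free,
        residuals=np.full(p, residual_start),
        residuals_free=np.ones(p, dtype=bool),
        identification=identification,
    )


def implied_covariance(spec: ModelSpec) -> ImpliedCovariance:
    """Σ = ΛΦΛ' + Θ of a fully numeric spec; must be positive definite."""
    if not spec.is_numeric:
        raise InvalidParameterError(
            f"{spec.name}: implied covariance requires a fully numeric spec"
        )
    sigma = spec.loadings @ spec.factor_cov @ spec.loadings.T + np.diag(spec.residuals)
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 0.0:
        raise DegeneracyError(
            f"{spec.name}: implied covariance is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.3e})",
            eigenvalue=float(eigvals[0]),
        )
    return ImpliedCovariance(sigma=sigma)


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free parameters q (factor covariances counted once)."""
    q = int(spec.loadings_free.sum())
    q += int(np.triu(spec.factor_cov_free).sum())
    q += int(spec.residuals_free.sum())
    return q


def model_df(spec: ModelSpec) -> int:
    """Degrees of freedom p(p+1)/2 − q of a fitted pattern."""
    p = spec.p
    df = p * (p + 1) // 2 - count_free_parameters(spec)
    if df < 0:
        raise UnderIdentifiedError(
            f"{spec.name}: {count_free_parameters(spec)} free parameters exceed "
            f"{p * (p + 1) // 2} sample moments"
        )
    return df


# ---------------------------------------------------------------------------
# Model-string dialect
#
#   line      := comment | loading | covariance
#   loading   := factor "=~" term ("+" term)*
#   covariance:= name "~~" term          (name ~~ name is a residual variance)
#   term      := (number "*")? name | "NA" "*" name
#
# A numeric prefix fixes the entry at that value; "NA*" or a bare name on the
# right-hand side marks it free.  Bare factor covariances default to free,
# matching lavaan's conventions.
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(NA|[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\*)?([A-Za-z_]\w*)$")


def _parse_term(tok: str, lineno: int):
    m = _TERM_RE.match(tok.strip())
    if not m:
        raise ModelSyntaxError(f"line {lineno}: cannot parse term {tok!r}")
    prefix, name = m.groups()
    if prefix is None or prefix == "NA":
        return name, None
    return name, float(prefix)


def parse_model(
    text: str,
    name: str = "model",
    identification: str = VARIANCE_STANDARDIZED,
) -> ModelSpec:
    """Parse the model-string dialect into a :class:`ModelSpec`.

    Factors are the left-hand sides of ``=~`` lines, in order of first
    appearance; indicators likewise.  Residual variances default to free,
    factor variances to fixed 1 (unless stated), factor covariances to free.
    """
    factors: list[str] = []
    indicators: list[str] = []
    loading_entries: dict[tuple[str, str], float | None] = {}
    cov_entries: dict[tuple[str, str], float | None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            factor = lhs.strip()
            if not re.match(r"^[A-Za-z_]\w*$", factor):
                raise ModelSyntaxError(f"line {lineno}: bad factor name {factor!r}")
            if factor not in factors:
                factors.append(factor)
            for tok in rhs.split("+"):
                ind, value = _parse_term(tok, lineno)
                if ind not in indicators:
                    indicators.append(ind)
                loading_entries[(ind, factor)] = value
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            left = lhs.strip()
            right, value = _parse_term(rhs, lineno)
            cov_entries[(left, right)] = value
        else:
            raise ModelSyntaxError(f"line {lineno}: expected '=~' or '~~' in {line!r}")

    if not factors:
        raise ModelSyntaxError("model defines no factors")
    p, m = len(indicators), len(factors)
    iidx = {t: i for i, t in enumerate(indicators)}
    fidx = {f: j for j, f in enumerate(factors)}

    loadings = np.zeros((p, m))
    loadings_free = np.zeros((p, m), dtype=bool)
    for (ind, factor), value in loading_entries.items():
        i, j = iidx[ind], fidx[factor]
        if value is None:
            loadings_free[i, j] = True
            loadings[i, j] = 0.5
        else:
            loadings[i, j] = value

    phi = np.eye(m)
    phi_free = ~np.eye(m, dtype=bool)
    residuals = np.full(p, 0.5)
    residuals_free = np.ones(p, dtype=bool)
    for (left, right), value in cov_entries.items():
        if left in fidx and right in fidx:
            j, k = fidx[left], fidx[right]
            if value is None:
                phi_free[j, k] = phi_free[k, j] = True
                if j != k:
                    phi[j, k] = phi[k, j] = 0.0
            else:
                phi_free[j, k] = phi_free[k, j] = False
                phi[j, k] = phi[k, j] = value
        elif left in iidx and right == left:
            i = iidx[left]
            if value is None:
                residuals_free[i] = True
            else:
                residuals_free[i] = False
                residuals[i] = value
        else:
            raise ModelSyntaxError(
                f"covariance {left!r} ~~ {right!r} refers to unknown or mixed names"
            )

    return ModelSpec(
        name=name,
        indicators=tuple(indicators),
        factors=tuple(factors),
        loadings=loadings,
        loadings_free=loadings_free,
        factor_cov=phi,
        factor_cov_free=phi_free,
        residuals=residuals,
        residuals_free=residuals_free,
        identification=identification,
    )


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def to_model_string(spec: ModelSpec) -> str:
    """Serialize a spec to the model-string dialect (round-trips parse_model)."""
    lines = []
    for j, factor in enumerate(spec.factors):
        terms = []
        for i, ind in enumerate(spec.indicators):
            if spec.loadings_free[i, j]:
                terms.append(f"NA*{ind}")
            elif spec.loadings[i, j] != 0.0:
                terms.append(f"{_fmt(spec.loadings[i, j])}*{ind}")
        if terms:
            lines.append(f"{factor} =~ " + " + ".join(terms))
    for j, fj in enumerate(spec.factors):
        for k in range(j, spec.m):
            fk = spec.factors[k]
            if spec.factor_cov_free[j, k]:
                if j == k:
                    lines.append(f"{fj} ~~ NA*{fk}")
                else:
                    lines.append(f"{fj} ~~ {fk}")
            elif j == k and spec.factor_cov[j, k] != 1.0:
                lines.append(f"{fj} ~~ {_fmt(spec.factor_cov[j, k])}*{fk}")
            elif j != k and spec.factor_cov[j, k] != 0.0:
                lines.append(f"{fj} ~~ {_fmt(spec.factor_cov[j, k])}*{fk}")
    for i, ind in enumerate(spec.indicators):
        if spec.residuals_free[i]:
            lines.append(f"{ind} ~~ NA*{ind}")
        else:
            lines.append(f"{ind} ~~ {_fmt(spec.residuals[i])}*{ind}")
    return "\n".join(lines) + "\n"
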