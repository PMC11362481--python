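"""Multivariate-normal data generation from a population model.

Rows are i.i.d. draws from N(0, Σ) where Σ is the model-implied covariance
of a fully numeric :class:`~sempower.model_zoo.ModelSpec`.  Sampling goes
through the Cholesky factor of Σ, so the target covariance is hit exactly in
population and the output is bit-reproducible given a seed.

Replication streams are derived with ``numpy``'s ``SeedSequence`` spawning
from ``(master_seed, condition_index, replication_index)``, which makes a
simulation reproducible regardless of how its replications are distributed
over workers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .model_zoo import ModelSpec, cross_loading_scale, implied_covariance

__all__ = ["Dataset", "cross_loading_scale", "generate", "replication_rng"]

SeedLike = int | np.random.SeedSequence | np.random.Generator


@dataclass(frozen=True)
class Dataset:
    """One simulated sample: an n × p matrix of standardized task scores."""

    values: np.ndarray
    n: int
    condition_id: str | None = None
    replication_index: int | None = None
    seed_state: str | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidParameterError("Dataset values must be a 2-D array")
        if values.shape[0] != self.n:
            raise InvalidParameterError(
                f"n={self.n} does not match {values.shape[0]} rows"
            )
        if np.isnan(values).any():
            raise InvalidParameterError("Dataset contains missing values")
        object.__setattr__(self, "values", values)
        values.setflags(write=False)

    @property
    def p(self) -> int:
        return self.values.shape[1]


def replication_rng(
    master_seed: int, condition_index: int, replication_index: int
) -> np.random.Generator:
    """Independent, reproducible stream for one replication of one condition.

    Spawned via ``SeedSequence(master_seed, spawn_key=(condition, rep))``;
    the stream depends only on the three integers, never on execution order
    or parallelism.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(condition_index), int(replication_index))
    )
    return np.random.default_rng(ss)


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate(
    spec: ModelSpec,
    n: int,
    seed: SeedLike,
    condition_id: str | None = None,
    replication_index: int | None = None,
) -> Dataset:
    """Draw an n × p sample from N(0, Σ(spec)).

    ``spec`` must be fully numeric.  Samples below p + 1 observations are
    allowed (the estimator may still be asked to fit them) but yield a
    singular sample covariance when n ≤ p.
    """
    if n < 1:
        raise InvalidParameterError(f"sample size must be positive, got {n}")
    sigma = implied_covariance(spec).sigma  # raises DegeneracyError if not PD
    chol = np.linalg.cholesky(sigma)
    rng = _as_rng(seed)
    z = rng.standard_normal((n, spec.p))
    return Dataset(
        values=z @ chol.T,
        n=n,
        condition_id=condition_id,
        replication_index=replication_index,
        seed_state=repr(seed) if not isinstance(seed, np.random.Generator) else None,
    )


def to_csv(dataset: Dataset, path, indicators=None) -> None:
    """Dump one replication to CSV (debugging aid; columns task1..taskp)."""
    import pandas as pd

    if indicators is None:
        indicators = [f"task{i}" for i in range(1, dataset.p + 1)]
    pd.DataFrame(dataset.values, columns=list(indicators)).to_csv(path, index=False)
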