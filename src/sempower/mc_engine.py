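"""Design grid, generate→fit→select loop, and power summaries.

A design is the full crossing of loading values ``a``, factor correlations
``r`` and sample sizes ``n`` for one generating model.  For every condition
and replication the engine simulates a dataset, fits the three candidate
models (unitary, bi-partite, tri-partite) by maximum likelihood, applies
the CFI/RMSEA/BIC selection rule, and records the outcome.  Summaries give
the proportion of replications selecting the generating model ("power" in
the model-selection sense) and the proportion selecting Model 3 (the
headline rate in type-I-error mode), each with its binomial Monte Carlo
standard error.

Replication streams are keyed on (master seed, condition index,
replication index), so results are identical for any degree of
parallelism.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import datagen, fit_indices, ml_estimator, model_zoo, selection
from .errors import InvalidParameterError

__all__ = [
    "DesignCondition",
    "MODEL_IDS",
    "build_design",
    "candidate_patterns",
    "population_model",
    "run",
    "summarize",
    "type_one_mode",
]

MODEL_IDS = (1, 2, 3)

RESULTS_SCHEMA = "sempower-results-v1"
SUMMARY_SCHEMA = "sempower-summary-v1"


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the simulation grid."""

    generating_model: int
    a: float
    r: float
    n: int
    replications: int

    def __post_init__(self):
        if self.generating_model not in MODEL_IDS:
            raise InvalidParameterError(
                f"generating_model must be one of {MODEL_IDS}, got {self.generating_model}"
            )
        if self.replications < 1:
            raise InvalidParameterError("replications must be >= 1")
        if self.n < 2:
            raise InvalidParameterError("sample size must be >= 2")


def build_design(
    a_grid: Sequence[float],
    r_grid: Sequence[float],
    n_grid: Sequence[int],
    generating_model: int,
    replications: int = 1000,
) -> list[DesignCondition]:
    """Full Cartesian crossing, ordered by a, then r, then n."""
    if not (len(a_grid) and len(r_grid) and len(n_grid)):
        raise InvalidParameterError("design grids must be non-empty")
    return [
        DesignCondition(generating_model, float(a), float(r), int(n), replications)
        for a, r, n in itertools.product(a_grid, r_grid, n_grid)
    ]


def population_model(cond: DesignCondition) -> model_zoo.ModelSpec:
    """The numeric population model for one condition."""
    if cond.generating_model == 1:
        return model_zoo.build_unitary(cond.a)
    if cond.generating_model == 2:
        return model_zoo.build_bipartite(cond.a, cond.r)
    return model_zoo.build_tripartite(cond.a, cond.r)


def candidate_patterns(
    identification: str = model_zoo.VARIANCE_STANDARDIZED,
) -> dict[int, model_zoo.ModelSpec]:
    """Fitted patterns of the three candidates (structure only, values free)."""
    return {
        1: model_zoo.free_pattern(model_zoo.build_unitary(0.5), identification),
        2: model_zoo.free_pattern(model_zoo.build_bipartite(0.5, 0.0), identification),
        3: model_zoo.free_pattern(model_zoo.build_tripartite(0.5, 0.0), identification),
    }


def _run_condition(
    cond: DesignCondition,
    cond_idx: int,
    master_seed: int,
    patterns: dict[int, model_zoo.ModelSpec],
    multiplier: str,
    store_indices: bool,
) -> list[dict]:
    pop = population_model(cond)
    rows = []
    for rep in range(cond.replications):
        rng = datagen.replication_rng(master_seed, cond_idx, rep)
        data = datagen.generate(
            pop, cond.n, rng, condition_id=str(cond_idx), replication_index=rep
        )
        S = ml_estimator.sample_cov(data)
        row = {
            "condition": cond_idx,
            "generating_model": cond.generating_model,
            "a": cond.a,
            "r": cond.r,
            "n": cond.n,
            "replication": rep,
        }
        cands = []
        try:
            base = ml_estimator.fit_baseline(S, cond.n, multiplier=multiplier)
            for mid in MODEL_IDS:
                fr = ml_estimator.fit_cov(
                    patterns[mid], S, cond.n, multiplier=multiplier
                )
                if fr.converged:
                    idx = fit_indices.compute_indices(fr, base, mid)
                    cand = selection.CandidateFit(
                        mid, True, idx.cfi, idx.rmsea, idx.bic, fr.q
                    )
                else:
                    cand = selection.CandidateFit(mid, False, q=fr.q)
                cands.append(cand)
                if store_indices:
                    row.update(
                        {
                            f"m{mid}_converged": fr.converged,
                            f"m{mid}_admissible": fr.admissible,
                            f"m{mid}_T": fr.T,
                            f"m{mid}_df": fr.df,
                            f"m{mid}_cfi": cand.cfi,
                            f"m{mid}_rmsea": cand.rmsea,
                            f"m{mid}_bic": cand.bic,
                        }
                    )
            outcome = selection.select(cands, cond.generating_model)
        except Exception:  # singular S or other statistical failure
            outcome = selection.SelectionOutcome(
                0, cond.generating_model, selection.REASON_NONCONVERGENCE
            )
        row["selected"] = outcome.selected
        row["reason"] = outcome.reason
        rows.append(row)
    return rows


def run(
    design: Sequence[DesignCondition],
    master_seed: int,
    parallelism: int = 1,
    *,
    identification: str = model_zoo.VARIANCE_STANDARDIZED,
    multiplier: str = "n",
    store_indices: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full generate→fit→select loop over a design.

    Returns one row per (condition, replication); the table is identical
    for any ``parallelism`` because every replication owns a seed stream
    derived from (master_seed, condition index, replication index).
    """
    if not design:
        raise InvalidParameterError("design is empty")
    patterns = candidate_patterns(identification)
    args = [
        (cond, i, master_seed, patterns, multiplier, store_indices)
        for i, cond in enumerate(design)
    ]

    def guarded(*a):
        # a crashed condition is flagged, not fatal: the run continues and
        # the failure surfaces in the result's attrs (CLI exits nonzero)
        try:
            return _run_condition(*a)
        except Exception as exc:  # pragma: no cover - defensive
            return ("failed", a[1], repr(exc))

    if parallelism == 1:
        chunks = []
        for a in args:
            chunks.append(guarded(*a))
            if progress and isinstance(chunks[-1], list):
                cond = a[0]
                sel = sum(r["selected"] == cond.generating_model for r in chunks[-1])
                print(
                    f"condition {a[1] + 1}/{len(design)}: "
                    f"model={cond.generating_model} a={cond.a} r={cond.r} n={cond.n} "
                    f"correct={sel}/{cond.replications}"
                )
    else:
        chunks = Parallel(n_jobs=parallelism)(delayed(guarded)(*a) for a in args)
    failed = [c for c in chunks if not isinstance(c, list)]
    df = pd.DataFrame(
        [row for chunk in chunks if isinstance(chunk, list) for row in chunk]
    )
    df.attrs["schema"] = RESULTS_SCHEMA
    df.attrs["master_seed"] = master_seed
    df.attrs["failed_conditions"] = [(c[1], c[2]) for c in failed]
    return df


def _proportion(mask: np.ndarray) -> tuple[float, float]:
    R = len(mask)
    phat = float(np.mean(mask))
    return phat, math.sqrt(phat * (1.0 - phat) / R)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition power table with Monte Carlo standard errors."""
    if results.empty:
        raise InvalidParameterError("results table is empty")
    rows = []
    keys = ["condition", "generating_model", "a", "r", "n"]
    for key, grp in results.groupby(keys, sort=True):
        cond = dict(zip(keys, key))
        correct, correct_se = _proportion(
            (grp["selected"] == grp["generating_model"]).to_numpy()
        )
        m3, m3_se = _proportion((grp["selected"] == 3).to_numpy())
        reasons = grp["reason"].value_counts()
        rows.append(
            {
                **cond,
                "replications": len(grp),
                "power_correct": correct,
                "power_mc_se": correct_se,
                "prop_model3": m3,
                "prop_model3_mc_se": m3_se,
                "n_chosen_by_bic": int(reasons.get(selection.REASON_BIC, 0)),
                "n_no_model_passed": int(reasons.get(selection.REASON_NO_PASS, 0)),
                "n_nonconvergence": int(
                    reasons.get(selection.REASON_NONCONVERGENCE, 0)
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["schema"] = SUMMARY_SCHEMA
    return out


def type_one_mode(
    design: Sequence[DesignCondition],
    master_seed: int,
    parallelism: int = 1,
    **kwargs,
) -> pd.DataFrame:
    """Power table for type-I-error designs (generating model 1 or 2).

    Identical machinery to :func:`run` + :func:`summarize`; the headline
    column is ``prop_model3``, the rate of erroneously selecting the
    tri-partite model.
    """
    if any(c.generating_model == 3 for c in design):
        raise InvalidParameterError(
            "type-I mode requires generating model 1 or 2 in every condition"
        )
    return summarize(run(design, master_seed, parallelism, **kwargs))
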