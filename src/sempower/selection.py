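"""The two-stage decision rule naming the best-fitting candidate model.

Stage (i): absolute fit — a candidate passes only with CFI > .95 and
RMSEA < .06 (strict inequalities; boundary values fail).  Stage (ii):
among passing candidates, the one with the strictly lowest BIC wins.  If
any candidate failed to converge the replication is scored 0 (no model
selected), as is an empty passing set.  The decision is a pure function of
its inputs and can be replayed from a stored results table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "CFI_CUTOFF",
    "RMSEA_CUTOFF",
    "CandidateFit",
    "SelectionOutcome",
    "select",
]

CFI_CUTOFF = 0.95
RMSEA_CUTOFF = 0.06

REASON_BIC = "chosen_by_bic"
REASON_NO_PASS = "no_model_passed_cutoffs"
REASON_NONCONVERGENCE = "nonconvergence"


@dataclass(frozen=True)
class CandidateFit:
    """What the rule needs to know about one candidate on one dataset."""

    model_id: int
    converged: bool
    cfi: float = float("nan")
    rmsea: float = float("nan")
    bic: float = float("nan")
    q: int = 0                 # free-parameter count, used only to break BIC ties


@dataclass(frozen=True)
class SelectionOutcome:
    """Selected model id for one replication; 0 means no model selected."""

    selected: int
    generating: int
    reason: str

    def __post_init__(self):
        if (self.selected == 0) == (self.reason == REASON_BIC):
            raise InvalidParameterError(
                f"selected={self.selected} inconsistent with reason={self.reason!r}"
            )


def _passes(c: CandidateFit) -> bool:
    if math.isnan(c.cfi) or math.isnan(c.rmsea):
        return False
    return c.cfi > CFI_CUTOFF and c.rmsea < RMSEA_CUTOFF


def select(candidates: list[CandidateFit], generating: int) -> SelectionOutcome:
    """Apply the cutoff-then-lowest-BIC rule to the three candidates.

    Any non-convergence voids the replication; BIC ties (a measure-zero
    event) go to the candidate with fewer free parameters, for determinism.
    """
    ids = [c.model_id for c in candidates]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError(f"duplicate candidate model ids: {ids}")
    if not candidates:
        raise InvalidParameterError("no candidates supplied")
    if any(not c.converged for c in candidates):
        return SelectionOutcome(0, generating, REASON_NONCONVERGENCE)
    passing = [c for c in candidates if _passes(c)]
    if not passing:
        return SelectionOutcome(0, generating, REASON_NO_PASS)
    winner = min(passing, key=lambda c: (c.bic, c.q, c.model_id))
    return SelectionOutcome(winner.model_id, generating, REASON_BIC)
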