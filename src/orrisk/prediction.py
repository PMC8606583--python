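"""Case scoring and classification against the decision boundary.

A case's risk score is the arithmetic mean of the odds ratios of all model
rules whose antecedent item occurs in the case. The decision function labels
the case *high-risk* when the mean OR reaches the decision boundary delta:

    f(p) = high-risk   if OR_p >= delta
           low-risk    if OR_p <  delta

Cases matching no rule at all receive the neutral score 1.0 (the
no-association OR), which is low-risk for any delta > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data_model import CaseRecord
from .mining import Rule, RuleModel

#: Score assigned to a case to which no rule applies.
NEUTRAL_SCORE = 1.0

HIGH_RISK = "high-risk"
LOW_RISK = "low-risk"


@dataclass(frozen=True)
class CasePrediction:
    """The scored, labelled outcome for one case, with its applying rules."""

    case_id: str
    applying_rules: Tuple[Rule, ...]
    score: float
    label: str

    @property
    def n_applying_rules(self) -> int:
        return len(self.applying_rules)


def applying_rules(model: RuleModel, case: CaseRecord) -> List[Rule]:
    """The model rules whose antecedent occurs in the case's item set.

    Sorted by (variable type, code) for stable reporting.
    """
    index = model.rule_index()
    hits = [index[item] for item in case.items if item in index]
    hits.sort(key=lambda r: r.sort_key)
    return hits


def score_case(model: RuleModel, case: CaseRecord) -> float:
    """Mean OR of the applying rules; :data:`NEUTRAL_SCORE` if none apply."""
    hits = applying_rules(model, case)
    if not hits:
        return NEUTRAL_SCORE
    return sum(r.or_value for r in hits) / len(hits)


def score_cases(model: RuleModel, cases: Sequence[CaseRecord]) -> np.ndarray:
    """Vector of scores for a case collection (index built once)."""
    index = {item: rule.or_value for item, rule in model.rule_index().items()}
    out = np.empty(len(cases), dtype=float)
    for i, case in enumerate(cases):
        total = 0.0
        n = 0
        for item in case.items:
            v = index.get(item)
            if v is not None:
                total += v
                n += 1
        out[i] = total / n if n else NEUTRAL_SCORE
    return out


def count_applying(model: RuleModel, cases: Sequence[CaseRecord]) -> np.ndarray:
    """Number of applying rules per case (the per-observation rule load)."""
    index = model.rule_index()
    return np.array(
        [sum(1 for item in case.items if item in index) for case in cases],
        dtype=int,
    )


def classify_case(
    model: RuleModel, case: CaseRecord, boundary: Optional[float] = None
) -> CasePrediction:
    """Score and label one case; ties at the boundary are high-risk.

    ``boundary`` overrides the model's stored decision boundary. If neither
    is set the model has not been calibrated and classification is refused.
    """
    delta = boundary if boundary is not None else model.decision_boundary
    if delta is None:
        raise ValueError(
            "no decision boundary set; calibrate one (e.g. via "
            "evaluation.youden_boundary on training scores) or pass boundary="
        )
    if not delta > 0:
        raise ValueError(f"decision boundary must be positive, got {delta}")
    hits = tuple(applying_rules(model, case))
    score = sum(r.or_value for r in hits) / len(hits) if hits else NEUTRAL_SCORE
    label = HIGH_RISK if score >= delta else LOW_RISK
    return CasePrediction(
        case_id=case.case_id, applying_rules=hits, score=score, label=label
    )
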