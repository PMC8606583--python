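"""Evaluation harness: splits, ROC/AUC, Youden boundary, grids, summaries.

The experimental protocol mirrors the study design the method was introduced
with: the case collection is repeatedly split at random into 90% training and
10% test (no stratification), rules are mined and filtered on the training
split for every combination of the p_max grid

    {0} U {10^-n : n = 0..10} U {0.05}

with Bonferroni correction on and off (26 configurations), and discrimination
is measured with the area under the ROC curve on both splits. The operating
point (decision boundary) is chosen on the training split by maximising the
Youden index J = sensitivity + specificity - 1.

AUC is computed with the Mann-Whitney rank statistic, counting ties as 1/2;
ties are common here because scores are means over a small shared rule pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import CaseRecord
from .mining import Rule, RuleModel, apply_filter, mine_candidates
from .prediction import count_applying, score_cases

#: The default p_max grid: 0, 10^0 .. 10^-10, and 0.05 (13 values).
DEFAULT_P_MAX_GRID: Tuple[float, ...] = (0.0,) + tuple(
    10.0 ** -n for n in range(0, 11)
) + (0.05,)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def split_cases(
    cases: Sequence[CaseRecord], test_fraction: float, seed: int
) -> Tuple[List[CaseRecord], List[CaseRecord]]:
    """Simple random, unstratified train/test partition (disjoint, exhaustive)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    cases = list(cases)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_test = int(round(len(cases) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [c for i, c in enumerate(cases) if i not in test_idx]
    test = [cases[i] for i in order[:n_test]]
    return train, test


# --------------------------------------------------------------------------
# ROC / AUC / operating point
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over the distinct score thresholds.

    ``thresholds`` are the distinct scores in descending order; at threshold
    t a case is called high-risk when its score is >= t. ``auc`` is the
    Mann-Whitney statistic P(score_death > score_survivor) + P(tie)/2, which
    equals the trapezoidal area under the curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_j: float
    youden_threshold: float

    def trapezoid_auc(self) -> float:
        """Area under the empirical curve (should equal ``auc``)."""
        fpr = np.concatenate(([0.0], 1.0 - self.specificity, [1.0]))
        tpr = np.concatenate(([0.0], self.sensitivity, [1.0]))
        return float(np.trapezoid(tpr, fpr))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Build the ROC curve and AUC for scores against binary death labels.

    ``labels`` is truthy for deaths (the positive class). Requires at least
    one case of each class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one death and one survivor")

    ranks = rankdata(scores)  # midranks: ties contribute 1/2
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # curve at each distinct score, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order].astype(float)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    last_of_group = np.concatenate((distinct, [len(scores) - 1]))
    tp = np.cumsum(sorted_pos)[last_of_group]
    fp = np.cumsum(1.0 - sorted_pos)[last_of_group]
    thresholds = sorted_scores[last_of_group]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg  # tn/N directly: exact ties matter for Youden

    j = sens + spec - 1.0
    best_j = j.max()
    # thresholds are descending; the last index attaining the max is the
    # smallest optimal threshold
    best_idx = np.nonzero(j == best_j)[0][-1]
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_j=float(best_j),
        youden_threshold=float(thresholds[best_idx]),
    )


def youden_boundary(roc: RocCurve) -> float:
    """The threshold maximising J = sensitivity + specificity - 1.

    Ties are broken towards the smallest optimal threshold.
    """
    return roc.youden_threshold


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[bool], boundary: float
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at the given boundary.

    High-risk (score >= boundary) is the positive, death-predicting class.
    """
    if not boundary > 0:
        raise ValueError(f"boundary must be positive, got {boundary}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= boundary
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    accuracy = (tp + tn) / len(labels)
    return accuracy, sensitivity, specificity


# --------------------------------------------------------------------------
# experiment grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentCell:
    """One (p_max, Bonferroni, repetition) cell of the experiment grid."""

    p_max: float
    bonferroni: bool
    repetition: int
    split_seed: int
    valid: bool
    n_rules: int = 0
    auc_train: float = float("nan")
    auc_test: float = float("nan")
    boundary: float = float("nan")
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    mean_applying_rules_per_case: float = float("nan")
    note: str = ""


def _has_both_classes(cases: Sequence[CaseRecord]) -> bool:
    deaths = sum(1 for c in cases if c.died)
    return 0 < deaths < len(cases)


def run_grid(
    cases: Sequence[CaseRecord],
    p_max_values: Optional[Sequence[float]] = None,
    bonferroni_options: Sequence[bool] = (False, True),
    repetitions: int = 10,
    model_class: str = "full",
    base_seed: int = 0,
    test_fraction: float = 0.1,
    models_out: Optional[Dict[Tuple[float, bool, int], RuleModel]] = None,
) -> List[ExperimentCell]:
    """Run the full evaluation protocol and return one cell per configuration.

    Candidates are mined once per repetition (the split, not the filter, is
    the expensive part) and re-filtered for every (p_max, bonferroni) pair.
    Degenerate splits — a train or test side missing one outcome class — are
    reported as invalid cells, never silently dropped. ``models_out``, if
    given, collects the fitted (boundary-calibrated) model of every valid
    cell keyed by (p_max, bonferroni, repetition).
    """
    if p_max_values is None:
        p_max_values = DEFAULT_P_MAX_GRID
    cases = list(cases)
    cells: List[ExperimentCell] = []
    for rep in range(repetitions):
        split_seed = int(base_seed) + rep
        train, test = split_cases(cases, test_fraction, split_seed)
        if not (_has_both_classes(train) and _has_both_classes(test)):
            for p_max in p_max_values:
                for bonf in bonferroni_options:
                    cells.append(
                        ExperimentCell(
                            p_max=p_max, bonferroni=bonf, repetition=rep,
                            split_seed=split_seed, valid=False,
                            note="degenerate split: a side lacks an outcome class",
                        )
                    )
            continue
        candidates = mine_candidates(train, model_class)
        train_labels = np.array([c.died for c in train])
        test_labels = np.array([c.died for c in test])
        for p_max in p_max_values:
            for bonf in bonferroni_options:
                model = apply_filter(candidates, p_max, bonf, model_class)
                train_scores = score_cases(model, train)
                test_scores = score_cases(model, test)
                roc_train = roc_auc(train_scores, train_labels)
                roc_test = roc_auc(test_scores, test_labels)
                delta = youden_boundary(roc_train)
                acc, sens, spec = confusion_metrics(test_scores, test_labels, delta) \
                    if delta > 0 else (float("nan"),) * 3
                cells.append(
                    ExperimentCell(
                        p_max=p_max,
                        bonferroni=bonf,
                        repetition=rep,
                        split_seed=split_seed,
                        valid=True,
                        n_rules=len(model),
                        auc_train=roc_train.auc,
                        auc_test=roc_test.auc,
                        boundary=delta,
                        accuracy=acc,
                        sensitivity=sens,
                        specificity=spec,
                        mean_applying_rules_per_case=float(
                            count_applying(model, test).mean()
                        ),
                    )
                )
                if models_out is not None:
                    models_out[(p_max, bonf, rep)] = model.with_boundary(delta) \
                        if delta > 0 else model
    return cells


def cells_to_frame(cells: Sequence[ExperimentCell]) -> pd.DataFrame:
    """Tidy one-row-per-cell results table."""
    return pd.DataFrame([vars(c) if not hasattr(c, "__dataclass_fields__")
                         else {f: getattr(c, f) for f in c.__dataclass_fields__}
                         for c in cells])


def aggregate_cells(cells: Sequence[ExperimentCell]) -> pd.DataFrame:
    """Mean and standard deviation across repetitions per configuration."""
    df = cells_to_frame(cells)
    df = df[df["valid"]]
    metrics = [
        "n_rules", "auc_train", "auc_test", "boundary",
        "accuracy", "sensitivity", "specificity",
        "mean_applying_rules_per_case",
    ]
    grouped = df.groupby(["p_max", "bonferroni"])[metrics]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


# --------------------------------------------------------------------------
# rule-set summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleSummary:
    """Descriptive statistics of a mined rule set."""

    n_rules: int
    counts_by_type: Dict[str, int]
    n_negative: int  # OR < 1
    n_positive: int  # OR > 1
    top_rules: Tuple[Rule, ...]
    bottom_rules: Tuple[Rule, ...]
    keyword_ranges: Dict[str, Tuple[int, float, float]]  # name -> (count, min, max)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable_type": t, "n_rules": n}
            for t, n in sorted(self.counts_by_type.items())
        ]
        return pd.DataFrame(rows)

    def format_text(self) -> str:
        lines = [f"rules: {self.n_rules} "
                 f"({self.n_negative} negative, {self.n_positive} positive)"]
        for t, n in sorted(self.counts_by_type.items()):
            lines.append(f"  {t:15s} {n}")
        if self.top_rules:
            lines.append("highest ORs:")
            for r in self.top_rules:
                lines.append(
                    f"  {r.antecedent.variable_type.value}:{r.antecedent.code}"
                    f"  OR={r.or_value:.2f}"
                )
            lines.append("lowest ORs:")
            for r in self.bottom_rules:
                lines.append(
                    f"  {r.antecedent.variable_type.value}:{r.antecedent.code}"
                    f"  OR={r.or_value:.2f}"
                )
        for name, (count, lo, hi) in sorted(self.keyword_ranges.items()):
            lines.append(f"group {name!r}: {count} rules, OR range {lo:.2f}-{hi:.2f}")
        return "\n".join(lines)


def summarize_rules(
    model: RuleModel,
    top_k: int = 5,
    keyword_groups: Optional[Dict[str, str]] = None,
) -> RuleSummary:
    """Summarise a rule set: per-type counts, OR sign split, extremes, groups.

    ``keyword_groups`` maps a group name to a case-insensitive substring
    matched against rule codes, reproducing grouped OR-range readouts such
    as "all sepsis rules span ORs 4.15-33.18".
    """
    counts: Counter = Counter(
        r.antecedent.variable_type.value for r in model.rules
    )
    n_negative = sum(1 for r in model.rules if r.or_value < 1.0)
    n_positive = sum(1 for r in model.rules if r.or_value > 1.0)
    by_or = sorted(model.rules, key=lambda r: r.or_value)
    keyword_ranges: Dict[str, Tuple[int, float, float]] = {}
    for name, substring in (keyword_groups or {}).items():
        needle = substring.lower()
        hits = [r for r in model.rules if needle in r.antecedent.code.lower()]
        if hits:
            ors = [r.or_value for r in hits]
            keyword_ranges[name] = (len(hits), min(ors), max(ors))
        else:
            keyword_ranges[name] = (0, float("nan"), float("nan"))
    return RuleSummary(
        n_rules=len(model),
        counts_by_type=dict(counts),
        n_negative=n_negative,
        n_positive=n_positive,
        top_rules=tuple(reversed(by_or[-top_k:])),
        bottom_rules=tuple(by_or[:top_k]),
        keyword_ranges=keyword_ranges,
    )
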