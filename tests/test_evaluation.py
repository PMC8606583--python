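"""Splits, ROC/AUC against brute-force oracles, Youden boundary, grid, summaries."""

import numpy as np
import pytest

from orrisk import (
    DEFAULT_P_MAX_GRID,
    aggregate_cells,
    cells_to_frame,
    confusion_metrics,
    mine_model,
    roc_auc,
    run_grid,
    split_cases,
    summarize_rules,
    youden_boundary,
)
from orrisk.mining import Rule, RuleModel
from orrisk import Item, VariableType


def brute_force_auc(scores, labels):
    """All-pairs P(score_death > score_survivor) with ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive sweep over all candidate thresholds; smallest maximiser."""
    best_j, best_t = -2.0, None
    for t in sorted(set(scores)):
        pred = [s >= t for s in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        tn = sum((not p) and (not l) for p, l in zip(pred, labels))
        sens = tp / sum(labels)
        spec = tn / (len(labels) - sum(labels))
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return best_j, best_t


# --------------------------------------------------------------------------
# split_cases
# --------------------------------------------------------------------------

def test_split_is_disjoint_exhaustive_and_reproducible(small_population):
    cases = small_population[:1000]
    train, test = split_cases(cases, 0.1, seed=5)
    assert len(train) == 900 and len(test) == 100
    ids = {c.case_id for c in train} | {c.case_id for c in test}
    assert len(ids) == 1000
    train2, test2 = split_cases(cases, 0.1, seed=5)
    assert train == train2 and test == test2


def test_different_seeds_give_different_partitions(small_population):
    cases = small_population[:1000]
    tests = [tuple(c.case_id for c in split_cases(cases, 0.1, s)[1])
             for s in range(5)]
    assert len(set(tests)) == 5


def test_bad_fraction_rejected(small_population):
    with pytest.raises(ValueError):
        split_cases(small_population, 1.0, seed=0)


# --------------------------------------------------------------------------
# roc_auc / youden / confusion
# --------------------------------------------------------------------------

def test_auc_trivial_cases():
    assert roc_auc([10, 9, 1, 2], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([3.0] * 6, [1, 0, 1, 0, 0, 0]).auc == 0.5
    curve = roc_auc([3, 1, 2, 2], [1, 0, 1, 0])
    assert curve.auc == pytest.approx((1 + 1 + 0.5 + 1) / 4 / 1)  # 4 pairs
    assert curve.auc == pytest.approx(brute_force_auc([3, 1, 2, 2], [1, 0, 1, 0]))


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_auc_matches_brute_force_and_reference_on_random_inputs():
    from sklearn.metrics import roc_auc_score  # independent reference

    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = rng.integers(4, 40)
        scores = rng.choice([0.5, 1.0, 1.5, 2.0, 3.0, 5.0], size=n)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
        if labels.all() or not labels.any():
            continue
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-10)
        assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)
        assert curve.auc == pytest.approx(curve.trapezoid_auc(), abs=1e-10)


def test_auc_invariances():
    rng = np.random.default_rng(7)
    scores = rng.random(50)
    labels = rng.random(50) < 0.3
    labels[0], labels[1] = True, False
    base = roc_auc(scores, labels).auc
    assert roc_auc(np.exp(3 * scores), labels).auc == pytest.approx(base)
    assert roc_auc(-scores, labels).auc == pytest.approx(1 - base)  # tie-free


def test_youden_perfect_separation_returns_smallest_optimal_threshold():
    curve = roc_auc([10, 9, 1, 2], [1, 1, 0, 0])
    assert curve.youden_j == 1.0
    assert youden_boundary(curve) == 9  # smallest threshold attaining J=1


def test_youden_all_ties_is_zero():
    curve = roc_auc([3.0] * 6, [1, 0, 1, 0, 0, 0])
    assert curve.youden_j == 0.0


def test_youden_matches_exhaustive_sweep_on_random_inputs():
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = int(rng.integers(6, 25))
        scores = list(rng.choice([0.4, 0.8, 1.0, 1.6, 2.5, 4.0], size=n))
        labels = list(rng.random(n) < 0.4)
        if all(labels) or not any(labels):
            continue
        curve = roc_auc(scores, labels)
        j, t = brute_force_youden(scores, labels)
        assert curve.youden_j == pytest.approx(j, abs=1e-12)
        assert youden_boundary(curve) == pytest.approx(t)


def test_confusion_metrics_hand_counted():
    scores = [5, 4, 3, 2.5, 2, 1.5, 1, 0.9, 0.8, 0.7] * 2
    labels = [1, 1, 0, 1, 0, 0, 0, 1, 0, 0] * 2
    acc, sens, spec = confusion_metrics(scores, labels, boundary=2.0)
    # predicted positive: scores >= 2 -> positions 0..4 (x2)
    assert sens == pytest.approx(6 / 8)
    assert spec == pytest.approx(8 / 12)
    assert acc == pytest.approx((6 + 8) / 20)


def test_confusion_extremes():
    scores = [10, 9, 1, 2]
    labels = [1, 1, 0, 0]
    assert confusion_metrics(scores, labels, 5) == (1.0, 1.0, 1.0)
    assert confusion_metrics(scores, labels, 0.5) == (0.5, 1.0, 0.0)


# --------------------------------------------------------------------------
# grid & summaries
# --------------------------------------------------------------------------

def test_default_grid_has_thirteen_p_values():
    assert len(DEFAULT_P_MAX_GRID) == 13
    assert 0.0 in DEFAULT_P_MAX_GRID and 0.05 in DEFAULT_P_MAX_GRID
    assert 1.0 in DEFAULT_P_MAX_GRID and 1e-10 in DEFAULT_P_MAX_GRID


def test_single_cell_grid(small_population):
    cells = run_grid(small_population[:2000], [0.05], [True],
                     repetitions=1, base_seed=3)
    assert len(cells) == 1
    cell = cells[0]
    assert cell.valid
    assert 0.0 <= cell.auc_test <= 1.0
    assert cell.n_rules >= 0 and cell.boundary > 0


def test_grid_n_rules_nondecreasing_in_p_max(small_population):
    p_values = [1e-8, 1e-4, 1e-2, 0.05, 1.0]
    cells = run_grid(small_population, p_values, [False],
                     repetitions=2, base_seed=1)
    by_rep = {}
    for c in cells:
        by_rep.setdefault(c.repetition, {})[c.p_max] = c.n_rules
    for counts in by_rep.values():
        ordered = [counts[p] for p in p_values]
        assert ordered == sorted(ordered)


def test_degenerate_split_is_flagged_not_dropped():
    from orrisk import build_itemset

    # 1 death in 10 cases: most splits leave one side single-class
    cases = [build_itemset([("ward", "W")], "died", "d0")] + [
        build_itemset([("ward", "W")], "survived", f"s{i}") for i in range(9)
    ]
    cells = run_grid(cases, [0.05], [False], repetitions=3, base_seed=0)
    assert len(cells) == 3
    assert all((c.valid or "degenerate" in c.note) for c in cells)


def test_aggregation_reports_mean_and_sd(small_population):
    cells = run_grid(small_population[:3000], [0.05, 1.0], [False],
                     repetitions=3, base_seed=2)
    agg = aggregate_cells(cells)
    assert set(agg["p_max"]) == {0.05, 1.0}
    assert "auc_test_mean" in agg.columns and "auc_test_std" in agg.columns
    df = cells_to_frame(cells)
    manual = df[(df.p_max == 0.05) & df.valid]["auc_test"].mean()
    assert agg[agg.p_max == 0.05]["auc_test_mean"].iloc[0] == pytest.approx(manual)


def _toy_model(ors):
    rules = tuple(
        Rule(Item(VariableType.DIAGNOSIS, f"d{i}"), v, 0.0)
        for i, v in enumerate(ors)
    )
    return RuleModel(rules, p_max=0.0, bonferroni=False, n_tests=len(rules))


def test_summarize_rules_counts_signs_and_groups():
    summary = summarize_rules(_toy_model([0.5, 2.0, 3.0]))
    assert summary.n_negative == 1 and summary.n_positive == 2
    assert summary.counts_by_type == {"diagnosis": 3}

    empty = summarize_rules(
        RuleModel((), p_max=0.0, bonferroni=False, n_tests=0)
    )
    assert empty.n_rules == 0 and empty.counts_by_type == {}

    model = mine_model_with_known_types()
    s = summarize_rules(model, keyword_groups={"seps": "sepsis"})
    count, lo, hi = s.keyword_ranges["seps"]
    assert count == 2 and lo == 2.0 and hi == 8.0


def mine_model_with_known_types():
    rules = (
        Rule(Item(VariableType.DIAGNOSIS, "Sepsis A"), 2.0, 0.0),
        Rule(Item(VariableType.DIAGNOSIS, "severe sepsis"), 8.0, 0.0),
        Rule(Item(VariableType.WARD, "ICU"), 5.0, 0.0),
    )
    return RuleModel(rules, p_max=0.0, bonferroni=False, n_tests=3)


def test_summary_counts_match_synthetic_construction(small_population):
    model = mine_model(small_population, "full", 1.0, False)
    summary = summarize_rules(model)
    assert sum(summary.counts_by_type.values()) == summary.n_rules == len(model)
    mined_types = {r.antecedent.variable_type.value for r in model.rules}
    assert set(summary.counts_by_type) == mined_types
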