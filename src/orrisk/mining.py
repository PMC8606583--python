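"""Rule mining: one-item association rules scored by the odds ratio.

For every distinct item occurring in a case collection a 2x2 contingency
table against the in-hospital mortality outcome is counted:

====================  ======  ==========
..                     died    survived
====================  ======  ==========
item present           a       b
item absent            c       d
====================  ======  ==========

The odds ratio OR = (a*d)/(b*c) measures the association between the item
and mortality (1 = none, >1 positive, <1 negative). Items with any zero
cell have an OR of 0 or infinity and are discarded outright — no continuity
correction is applied. The surviving candidates are tested against the null
hypothesis OR = 1 with the normal approximation of the log odds ratio
(Woolf standard error), and only rules whose two-sided p-value falls below
the configured threshold are kept in the model. Bonferroni correction
optionally divides the threshold by the number of tests actually executed.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from scipy.stats import norm

from .data_model import CaseRecord, Item, VariableType, coerce_variable_type

MODEL_CLASSES = ("minimal", "full")


class _UndefinedOddsRatio:
    """Sentinel for an OR of 0 or infinity (some contingency cell is zero).

    Distinct from every number; rules carrying it are discarded by mining.
    """

    _instance: "_UndefinedOddsRatio | None" = None

    def __new__(cls) -> "_UndefinedOddsRatio":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED_OR"

    def __bool__(self) -> bool:
        return False


#: Returned by :func:`odds_ratio` when any contingency cell is zero.
UNDEFINED_OR = _UndefinedOddsRatio()


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts of item presence vs. in-hospital mortality."""

    a: int  # item present, died
    b: int  # item present, survived
    c: int  # item absent, died
    d: int  # item absent, survived

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def deaths(self) -> int:
        return self.a + self.c

    @property
    def survivors(self) -> int:
        return self.b + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def tabulate(item: Item, cases: Sequence[CaseRecord]) -> ContingencyTable:
    """Count the contingency table of one item over a case collection."""
    if not cases:
        raise ValueError("cases must be non-empty")
    a = b = c = d = 0
    for case in cases:
        present = item in case.items
        if case.died:
            if present:
                a += 1
            else:
                c += 1
        elif present:
            b += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def odds_ratio(table: ContingencyTable) -> Union[float, _UndefinedOddsRatio]:
    """Cross-product ratio (a*d)/(b*c); :data:`UNDEFINED_OR` on any zero cell."""
    if table.has_zero_cell():
        return UNDEFINED_OR
    return (table.a * table.d) / (table.b * table.c)


def log_or_test(table: ContingencyTable) -> float:
    """Two-sided p-value for the null OR = 1 via the normal approximation.

    z = ln(OR) / SE with the Woolf large-sample standard error
    SE = sqrt(1/a + 1/b + 1/c + 1/d). The returned value may underflow to
    exactly 0.0 for overwhelming evidence; that underflow is meaningful (the
    strictest filter configuration keeps exactly those rules).
    """
    if table.has_zero_cell():
        raise ValueError("log_or_test requires all four cells positive; "
                         "zero-cell rules must be discarded before testing")
    log_or = math.log(table.a) + math.log(table.d) - math.log(table.b) - math.log(table.c)
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = abs(log_or) / se
    return min(1.0, 2.0 * float(norm.sf(z)))


@dataclass(frozen=True, slots=True)
class Rule:
    """One association "item => in-hospital mortality" with its OR and p-value.

    ``table`` is None only for rules transcribed from published model
    listings, where the underlying counts are not available.
    """

    antecedent: Item
    or_value: float
    p_value: float
    table: Optional[ContingencyTable] = None

    def __post_init__(self) -> None:
        if not (self.or_value > 0 and math.isfinite(self.or_value)):
            raise ValueError(f"or_value must be positive and finite, got {self.or_value}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if self.table is not None:
            expected = odds_ratio(self.table)
            if expected is UNDEFINED_OR or not math.isclose(
                self.or_value, expected, rel_tol=1e-12
            ):
                raise ValueError(
                    "or_value does not match (a*d)/(b*c) of the stored table"
                )

    @property
    def sort_key(self) -> Tuple[str, str]:
        return (self.antecedent.variable_type.value, self.antecedent.code)


def _rule_sorted(rules: Iterable[Rule]) -> Tuple[Rule, ...]:
    return tuple(sorted(rules, key=lambda r: r.sort_key))


@dataclass(frozen=True)
class RuleModel:
    """A filtered rule set plus its mining configuration.

    ``n_tests`` records how many hypothesis tests were executed (candidates
    after zero-cell discard), which is also the Bonferroni denominator.
    ``decision_boundary`` is the score threshold delta of the decision
    function; it stays None until calibrated.
    """

    rules: Tuple[Rule, ...]
    p_max: float
    bonferroni: bool
    n_tests: int
    model_class: str = "full"
    decision_boundary: Optional[float] = None
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", _rule_sorted(self.rules))
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        if self.model_class == "minimal":
            for r in self.rules:
                if not r.antecedent.variable_type.minimal_class:
                    raise ValueError(
                        "minimal model contains a non-minimal-class antecedent: "
                        f"{r.antecedent}"
                    )
        if self.decision_boundary is not None and not self.decision_boundary > 0:
            raise ValueError("decision_boundary must be positive")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def effective_threshold(self) -> float:
        """The p-value cut actually applied (p_max, Bonferroni-divided if on)."""
        if self.bonferroni and self.n_tests > 0:
            return self.p_max / self.n_tests
        return self.p_max

    def rule_index(self) -> Dict[Item, Rule]:
        """Map antecedent item -> rule, for membership lookups when scoring."""
        return {r.antecedent: r for r in self.rules}

    def with_boundary(self, boundary: float) -> "RuleModel":
        return replace(self, decision_boundary=float(boundary))

    # ----- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {
            "model_class": self.model_class,
            "p_max": self.p_max,
            "bonferroni": self.bonferroni,
            "n_tests": self.n_tests,
            "decision_boundary": self.decision_boundary,
            "rules": [
                {
                    "variable_type": r.antecedent.variable_type.value,
                    "code": r.antecedent.code,
                    "or": r.or_value,
                    "p_value": r.p_value,
                    "a": r.table.a if r.table else None,
                    "b": r.table.b if r.table else None,
                    "c": r.table.c if r.table else None,
                    "d": r.table.d if r.table else None,
                }
                for r in self.rules
            ],
        }
        if self.provenance is not None:
            out["provenance"] = self.provenance
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RuleModel":
        rules = []
        for rd in data["rules"]:
            cells = (rd.get("a"), rd.get("b"), rd.get("c"), rd.get("d"))
            table = None if any(v is None for v in cells) else ContingencyTable(*cells)
            rules.append(
                Rule(
                    antecedent=Item(coerce_variable_type(rd["variable_type"]), rd["code"]),
                    or_value=float(rd["or"]),
                    p_value=float(rd["p_value"]),
                    table=table,
                )
            )
        return cls(
            rules=tuple(rules),
            p_max=float(data["p_max"]),
            bonferroni=bool(data["bonferroni"]),
            n_tests=int(data["n_tests"]),
            model_class=data.get("model_class", "full"),
            decision_boundary=data.get("decision_boundary"),
            provenance=data.get("provenance"),
        )

    def to_json(self) -> str:
        """Canonical JSON form; byte-stable round trip through ``from_json``."""
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RuleModel":
        return cls.from_dict(json.loads(text))


def mine_candidates(
    cases: Sequence[CaseRecord], model_class: str = "full"
) -> List[Rule]:
    """Mine one candidate rule per distinct item with all-positive cells.

    Items whose OR would be 0 or infinity (any zero contingency cell) yield
    no candidate. With ``model_class="minimal"`` only items of the five
    admission-time demographic types are considered. The returned list is
    deterministically sorted by (variable type, code).
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
    cases = list(cases)
    if not cases:
        raise ValueError("cases must be non-empty")
    n_deaths = sum(1 for c in cases if c.died)
    n_survivors = len(cases) - n_deaths
    if n_deaths == 0 or n_survivors == 0:
        raise ValueError(
            "cases must contain at least one death and one survivor; "
            f"got {n_deaths} deaths / {n_survivors} survivors"
        )

    minimal_only = model_class == "minimal"
    deaths_with: Counter = Counter()
    survivors_with: Counter = Counter()
    for case in cases:
        items = case.items
        if minimal_only:
            items = [i for i in items if i.variable_type.minimal_class]
        if case.died:
            deaths_with.update(items)
        else:
            survivors_with.update(items)

    candidates: List[Rule] = []
    all_items = set(deaths_with) | set(survivors_with)
    for item in sorted(all_items, key=lambda i: (i.variable_type.value, i.code)):
        a = deaths_with.get(item, 0)
        b = survivors_with.get(item, 0)
        table = ContingencyTable(a, b, n_deaths - a, n_survivors - b)
        if table.has_zero_cell():
            continue
        candidates.append(
            Rule(
                antecedent=item,
                or_value=odds_ratio(table),
                p_value=log_or_test(table),
                table=table,
            )
        )
    return candidates


def apply_filter(
    candidates: Sequence[Rule],
    p_max: float,
    bonferroni: bool,
    model_class: str = "full",
) -> RuleModel:
    """Filter candidates by significance into a :class:`RuleModel`.

    Keeps rules with p-value strictly below the effective threshold
    (p_max, or p_max divided by the number of tests when Bonferroni
    correction is on). The special configuration ``p_max = 0`` keeps exactly
    the rules whose p-value underflowed to 0.0 — the strictest filter the
    floating-point representation allows — and is unaffected by Bonferroni.
    """
    if not (0.0 <= p_max <= 1.0):
        raise ValueError(f"p_max must lie in [0, 1], got {p_max}")
    n_tests = len(candidates)
    if p_max == 0.0:
        kept = [r for r in candidates if r.p_value == 0.0]
    else:
        threshold = p_max / n_tests if (bonferroni and n_tests) else p_max
        kept = [r for r in candidates if r.p_value < threshold]
    return RuleModel(
        rules=tuple(kept),
        p_max=float(p_max),
        bonferroni=bool(bonferroni),
        n_tests=n_tests,
        model_class=model_class,
    )


def mine_model(
    cases: Sequence[CaseRecord],
    model_class: str = "full",
    p_max: float = 0.05,
    bonferroni: bool = True,
) -> RuleModel:
    """Convenience: mine candidates and filter them in one step."""
    return apply_filter(
        mine_candidates(cases, model_class), p_max, bonferroni, model_class
    )
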