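"""Synthetic EHR-like case populations with planted item-mortality odds ratios.

The generator emulates the *statistical* shape of a large emergency/critical
care population: a rare binary in-hospital mortality outcome (default base
rate 1.79%), five demographic variable families in which every case carries
exactly one category (gender, ethnicity, insurance type, language, marital
status), and five clinical variable types (diagnosis, prescription,
procedure, service, ward) whose items occur independently with mostly low
prevalence and planted odds ratios spanning several orders of magnitude.

Items are generated conditionally independent given the outcome. For an
independent item with survivor prevalence q and planted OR rho, the
prevalence among deaths is the odds-scaled

    p = rho * q / (1 - q + rho * q),

so the population 2x2 table recovers rho exactly in expectation. Categories
inside a demographic family are mutually exclusive; their death-side
distribution is obtained by reweighting the survivor-side distribution with
per-category weights, and the *realised* per-category OR (computable exactly
from the two categorical distributions) is what the truth table reports.

Realistic clinical co-occurrence structure (comorbidity networks, temporal
ordering, code semantics) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import CaseRecord, Item, VariableType

#: In-hospital mortality base rate of the emulated population.
DEFAULT_BASE_MORTALITY = 0.0179


def death_prevalence(q: float, rho: float) -> float:
    """Prevalence among deaths implied by survivor prevalence q and OR rho.

    Solves [p/(1-p)] / [q/(1-q)] = rho for p.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"survivor prevalence must lie in (0, 1), got {q}")
    if not rho > 0:
        raise ValueError(f"planted OR must be positive, got {rho}")
    return rho * q / (1.0 - q + rho * q)


@dataclass(frozen=True)
class VariableSpec:
    """One independently-occurring item with survivor prevalence q and OR rho."""

    item: Item
    prevalence_survivors: float
    planted_or: float

    def __post_init__(self) -> None:
        # validates q and rho; implied p always lands in (0, 1)
        death_prevalence(self.prevalence_survivors, self.planted_or)

    @property
    def prevalence_deaths(self) -> float:
        return death_prevalence(self.prevalence_survivors, self.planted_or)


@dataclass(frozen=True)
class CategoricalFamily:
    """A mutually exclusive variable family (one category per case).

    ``survivor_probs`` is the category distribution among survivors (sums
    to 1). ``or_weights`` reweights it on the death side:
    p_k = w_k q_k / sum_j w_j q_j. Because the categories share one
    multinomial, the realised per-category OR differs from the raw weight;
    :meth:`realized_or` computes it exactly from the two distributions.
    """

    variable_type: VariableType
    codes: Tuple[str, ...]
    survivor_probs: Tuple[float, ...]
    or_weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.codes) == len(self.survivor_probs) == len(self.or_weights)):
            raise ValueError("codes, survivor_probs and or_weights must align")
        q = np.asarray(self.survivor_probs, dtype=float)
        w = np.asarray(self.or_weights, dtype=float)
        if np.any(q <= 0) or not np.isclose(q.sum(), 1.0, atol=1e-9):
            raise ValueError("survivor_probs must be positive and sum to 1")
        if np.any(w <= 0):
            raise ValueError("or_weights must be positive")

    @property
    def death_probs(self) -> Tuple[float, ...]:
        q = np.asarray(self.survivor_probs, dtype=float)
        w = np.asarray(self.or_weights, dtype=float)
        p = w * q
        return tuple(p / p.sum())

    def realized_or(self, k: int) -> float:
        """Exact population OR of category k vs. the mortality outcome."""
        q = self.survivor_probs[k]
        p = self.death_probs[k]
        return (p / (1.0 - p)) / (q / (1.0 - q))

    def items(self) -> Tuple[Item, ...]:
        return tuple(Item(self.variable_type, c) for c in self.codes)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic population."""

    n_cases: int
    base_mortality: float = DEFAULT_BASE_MORTALITY
    variables: Tuple[VariableSpec, ...] = ()
    families: Tuple[CategoricalFamily, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0.0 < self.base_mortality < 1.0:
            raise ValueError("base_mortality must lie in (0, 1)")

    def truth_table(self) -> pd.DataFrame:
        """Per-item ground truth: q, p and the exact population OR."""
        rows = []
        for spec in self.variables:
            rows.append(
                {
                    "variable_type": spec.item.variable_type.value,
                    "code": spec.item.code,
                    "prevalence_survivors": spec.prevalence_survivors,
                    "prevalence_deaths": spec.prevalence_deaths,
                    "population_or": spec.planted_or,
                }
            )
        for fam in self.families:
            death_probs = fam.death_probs
            for k, code in enumerate(fam.codes):
                rows.append(
                    {
                        "variable_type": fam.variable_type.value,
                        "code": code,
                        "prevalence_survivors": fam.survivor_probs[k],
                        "prevalence_deaths": death_probs[k],
                        "population_or": fam.realized_or(k),
                    }
                )
        return pd.DataFrame(rows)


def generate_population(config: SyntheticConfig) -> List[CaseRecord]:
    """Draw a fully reproducible case population from ``config``.

    All randomness flows from ``config.seed`` through a hierarchical
    ``SeedSequence``: one child stream for the outcomes, then one per
    variable and one per family, so adding a variable does not perturb the
    draws of the others.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.variables) + len(config.families))
    n = config.n_cases

    outcome_rng = np.random.default_rng(children[0])
    died = outcome_rng.random(n) < config.base_mortality

    item_lists: List[List[Item]] = [[] for _ in range(n)]

    for vi, spec in enumerate(config.variables):
        rng = np.random.default_rng(children[1 + vi])
        prob = np.where(died, spec.prevalence_deaths, spec.prevalence_survivors)
        present = rng.random(n) < prob
        item = spec.item  # shared instance
        for idx in np.nonzero(present)[0]:
            item_lists[idx].append(item)

    offset = 1 + len(config.variables)
    for fi, fam in enumerate(config.families):
        rng = np.random.default_rng(children[offset + fi])
        q = np.asarray(fam.survivor_probs)
        p = np.asarray(fam.death_probs)
        # inverse-CDF draw so survivors and deaths share one uniform stream
        u = rng.random(n)
        cat = np.empty(n, dtype=int)
        cat[~died] = np.searchsorted(np.cumsum(q), u[~died], side="right")
        cat[died] = np.searchsorted(np.cumsum(p), u[died], side="right")
        np.clip(cat, 0, len(fam.codes) - 1, out=cat)
        fam_items = fam.items()
        for idx in range(n):
            item_lists[idx].append(fam_items[cat[idx]])

    width = len(str(n - 1)) if n > 1 else 1
    return [
        CaseRecord(
            case_id=f"case-{i:0{width}d}",
            items=frozenset(item_lists[i]),
            died=bool(died[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# ready-made MIMIC-like configurations
# --------------------------------------------------------------------------

_SCALES = {
    # (n_cases, diagnosis, prescription, procedure, service, ward)
    "small": (5_000, 40, 30, 15, 5, 10),
    "medium": (50_000, 450, 350, 150, 15, 35),
}


def _demographic_families() -> Tuple[CategoricalFamily, ...]:
    """The five admission-time families (18 category items in total)."""
    return (
        CategoricalFamily(
            VariableType.GENDER,
            ("Male", "Female"),
            (0.52, 0.48),
            (1.25, 0.80),
        ),
        CategoricalFamily(
            VariableType.ETHNICITY,
            ("White", "Black/African American", "Hispanic/Latino",
             "Asian", "Unknown", "Unable to obtain"),
            (0.65, 0.12, 0.08, 0.05, 0.07, 0.03),
            (1.00, 0.58, 0.47, 1.00, 4.59, 2.25),
        ),
        CategoricalFamily(
            VariableType.INSURANCE_TYPE,
            ("Medicare", "Medicaid", "Other"),
            (0.45, 0.15, 0.40),
            (2.40, 0.57, 0.50),
        ),
        CategoricalFamily(
            VariableType.LANGUAGE,
            ("English", "Other"),
            (0.90, 0.10),
            (0.73, 1.36),
        ),
        CategoricalFamily(
            VariableType.MARITAL_STATUS,
            ("Married", "Single", "Widowed", "Divorced", "Missing"),
            (0.45, 0.30, 0.10, 0.10, 0.05),
            (1.00, 0.50, 2.05, 1.20, 1.00),
        ),
    )


def _clinical_variables(
    rng: np.random.Generator,
    variable_type: VariableType,
    prefix: str,
    count: int,
    prevalence_range: Tuple[float, float],
) -> List[VariableSpec]:
    lo, hi = prevalence_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=count))
    # mostly harmful effects, a minority protective, echoing a critical-care
    # population where clinical interventions flag severity
    positive = rng.random(count) < 0.8
    rho = np.where(
        positive,
        np.exp(rng.uniform(np.log(1.0), np.log(50.0), size=count)),
        np.exp(rng.uniform(np.log(0.05), np.log(1.0), size=count)),
    )
    width = len(str(count - 1)) if count > 1 else 1
    return [
        VariableSpec(
            item=Item(variable_type, f"{prefix}{i:0{width}d}"),
            prevalence_survivors=float(q[i]),
            planted_or=float(rho[i]),
        )
        for i in range(count)
    ]


def mimic_like_config(scale: str = "small", seed: int = 0) -> SyntheticConfig:
    """A ready-made population config with MIMIC-like statistical shape.

    ``small`` is ~5,000 cases over ~120 items; ``medium`` is ~50,000 cases
    over ~1,000 items. The five demographic families carry mild effects
    (category ORs roughly 0.5-2.5, at most 18 < 20 minimal-class items);
    the clinical types carry many mostly-rare items with planted ORs from
    0.05 to 50. The item universe itself is deterministic — it depends only
    on ``scale`` — while ``seed`` drives the population draw.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}, got {scale!r}")
    n_cases, n_diag, n_rx, n_proc, n_svc, n_ward = _SCALES[scale]
    spec_rng = np.random.default_rng(7_654_321)  # fixed: config is deterministic
    variables: List[VariableSpec] = []
    variables += _clinical_variables(
        spec_rng, VariableType.DIAGNOSIS, "ICD-", n_diag, (0.002, 0.15)
    )
    variables += _clinical_variables(
        spec_rng, VariableType.PRESCRIPTION, "RX-", n_rx, (0.002, 0.20)
    )
    variables += _clinical_variables(
        spec_rng, VariableType.PROCEDURE, "PROC-", n_proc, (0.002, 0.10)
    )
    variables += _clinical_variables(
        spec_rng, VariableType.SERVICE, "SVC-", n_svc, (0.01, 0.30)
    )
    variables += _clinical_variables(
        spec_rng, VariableType.WARD, "WARD-", n_ward, (0.01, 0.40)
    )
    return SyntheticConfig(
        n_cases=n_cases,
        base_mortality=DEFAULT_BASE_MORTALITY,
        variables=tuple(variables),
        families=_demographic_families(),
        seed=seed,
    )
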