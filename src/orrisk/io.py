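"""Reading and writing the package's file formats.

Formats:

* **Long-format case table** (TSV by default; CSV for ``.csv`` paths):
  columns ``case_id``, ``variable_type``, ``code``, ``outcome``, one row per
  case event. ``outcome`` accepts ``died``/``survived`` or ``1``/``0``.
  Rows with an empty ``variable_type``/``code`` contribute no item, which
  lets cases with empty item sets round-trip. Lines starting with ``#`` are
  provenance comments and are skipped.
* **Itemset JSON**: ``[{"case_id", "outcome", "items": [{"variable_type",
  "code"}, ...]}, ...]``.
* **Rule model JSON**: the canonical :meth:`RuleModel.to_json` form, plus a
  flat CSV rule table for human review.
* **Synthetic config JSON** (schema version 1) and a truth CSV listing each
  item's survivor/death prevalence and population OR.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .data_model import (
    CaseRecord,
    Item,
    VariableType,
    build_itemset,
    coerce_variable_type,
    parse_outcome,
)
from .mining import RuleModel
from .synthetic import CategoricalFamily, SyntheticConfig, VariableSpec

PathLike = Union[str, Path]

CASE_COLUMNS = ("case_id", "variable_type", "code", "outcome")

CONFIG_SCHEMA_VERSION = 1


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# --------------------------------------------------------------------------
# cases
# --------------------------------------------------------------------------

def read_cases(path: PathLike) -> List[CaseRecord]:
    """Read a long-format delimited case table into case records."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#",
                     keep_default_na=False)
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s): {', '.join(missing)}; "
            f"expected columns {', '.join(CASE_COLUMNS)}"
        )
    cases: List[CaseRecord] = []
    for case_id, group in df.groupby("case_id", sort=True):
        outcomes = {parse_outcome(v) for v in group["outcome"]}
        if len(outcomes) != 1:
            raise ValueError(f"{path}: case {case_id!r} has conflicting outcomes")
        events = [
            (vt, code)
            for vt, code in zip(group["variable_type"], group["code"])
            if vt != ""
        ]
        cases.append(build_itemset(events, outcomes.pop(), str(case_id)))
    return cases


def write_cases(
    cases: Sequence[CaseRecord], path: PathLike, header_comment: Optional[str] = None
) -> None:
    """Write case records as a long-format delimited table."""
    path = Path(path)
    sep = _sep_for(path)
    rows = []
    for case in cases:
        items = sorted(case.items, key=lambda i: (i.variable_type.value, i.code))
        if not items:
            rows.append((case.case_id, "", "", case.outcome))
        for item in items:
            rows.append(
                (case.case_id, item.variable_type.value, item.code, case.outcome)
            )
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(sep.join(CASE_COLUMNS) + "\n")
        for row in rows:
            fh.write(sep.join(row) + "\n")


def read_cases_json(path: PathLike) -> List[CaseRecord]:
    """Read the itemset JSON form (supports empty item sets natively)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        build_itemset(
            [(it["variable_type"], it["code"]) for it in entry.get("items", [])],
            entry["outcome"],
            entry["case_id"],
        )
        for entry in data
    ]


def write_cases_json(cases: Sequence[CaseRecord], path: PathLike) -> None:
    data = [
        {
            "case_id": case.case_id,
            "outcome": case.outcome,
            "items": [
                {"variable_type": i.variable_type.value, "code": i.code}
                for i in sorted(
                    case.items, key=lambda i: (i.variable_type.value, i.code)
                )
            ],
        }
        for case in cases
    ]
    Path(path).write_text(
        json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# --------------------------------------------------------------------------
# rule models
# --------------------------------------------------------------------------

def save_model(model: RuleModel, path: PathLike) -> None:
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_model(path: PathLike) -> RuleModel:
    return RuleModel.from_json(Path(path).read_text(encoding="utf-8"))


def rules_to_csv(model: RuleModel, path: PathLike) -> None:
    """Flat rule table (one row per rule) for human review."""
    rows = [
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
        for r in model.rules
    ]
    pd.DataFrame(rows, columns=["variable_type", "code", "or", "p_value",
                                "a", "b", "c", "d"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# synthetic configs & truth tables
# --------------------------------------------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "n_cases": config.n_cases,
        "base_mortality": config.base_mortality,
        "seed": config.seed,
        "variables": [
            {
                "variable_type": v.item.variable_type.value,
                "code": v.item.code,
                "prevalence_survivors": v.prevalence_survivors,
                "planted_or": v.planted_or,
            }
            for v in config.variables
        ],
        "families": [
            {
                "variable_type": f.variable_type.value,
                "codes": list(f.codes),
                "survivor_probs": list(f.survivor_probs),
                "or_weights": list(f.or_weights),
            }
            for f in config.families
        ],
    }


def config_from_dict(data: dict) -> SyntheticConfig:
    version = data.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    return SyntheticConfig(
        n_cases=int(data["n_cases"]),
        base_mortality=float(data.get("base_mortality", 0.0179)),
        seed=int(data.get("seed", 0)),
        variables=tuple(
            VariableSpec(
                item=Item(coerce_variable_type(v["variable_type"]), v["code"]),
                prevalence_survivors=float(v["prevalence_survivors"]),
                planted_or=float(v["planted_or"]),
            )
            for v in data.get("variables", [])
        ),
        families=tuple(
            CategoricalFamily(
                variable_type=coerce_variable_type(f["variable_type"]),
                codes=tuple(f["codes"]),
                survivor_probs=tuple(float(x) for x in f["survivor_probs"]),
                or_weights=tuple(float(x) for x in f["or_weights"]),
            )
            for f in data.get("families", [])
        ),
    )


def save_config(config: SyntheticConfig, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(config_to_dict(config), indent=2) + "\n", encoding="utf-8"
    )


def load_config(path: PathLike) -> SyntheticConfig:
    return config_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_truth(config: SyntheticConfig, path: PathLike) -> None:
    """Write the per-item ground-truth table (q, p, population OR) as CSV."""
    config.truth_table().to_csv(path, index=False)
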