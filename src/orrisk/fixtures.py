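"""Published example rule models and the worked fictional patient.

These fixtures transcribe the rules quoted in the study that introduced the
method: the 13-rule minimal (admission-time demographics) model, the four
clinical rules of the worked patient example, and the two Youden-calibrated
decision boundaries (1.015 minimal, 5.306 full). They exist so the worked
example can be reproduced and so prediction/reporting paths can be exercised
without mining.

The published listings give ORs but not p-values or contingency counts, so
transcribed rules carry ``p_value = 0.0`` and ``table = None`` and must not
be treated as mined output (``provenance.transcribed`` marks this).
"""

from __future__ import annotations

from .data_model import CaseRecord, Item, VariableType, build_itemset
from .mining import Rule, RuleModel

MINIMAL_BOUNDARY = 1.015
FULL_BOUNDARY = 5.306

#: The 13 published minimal-model rules: (variable type, code, OR).
_MINIMAL_RULES = (
    (VariableType.GENDER, "Male", 1.25),
    (VariableType.GENDER, "Female", 0.80),
    (VariableType.LANGUAGE, "English", 0.73),
    (VariableType.LANGUAGE, "Other", 1.36),
    (VariableType.INSURANCE_TYPE, "Medicare", 2.40),
    (VariableType.INSURANCE_TYPE, "Medicaid", 0.57),
    (VariableType.INSURANCE_TYPE, "Other", 0.50),
    (VariableType.ETHNICITY, "Hispanic/Latino", 0.47),
    (VariableType.ETHNICITY, "Black/African American", 0.58),
    (VariableType.ETHNICITY, "Unknown", 4.59),
    (VariableType.ETHNICITY, "Unable to obtain", 2.25),
    (VariableType.MARITAL_STATUS, "Widowed", 2.05),
    (VariableType.MARITAL_STATUS, "Single", 0.50),
)

#: The published clinical rules applying to the worked fictional patient.
_CLINICAL_RULES = (
    (VariableType.DIAGNOSIS, "Acidosis", 10.96),
    (VariableType.DIAGNOSIS, "Anuria and oliguria", 17.27),
    (VariableType.PRESCRIPTION, "Sodium Bicarbonate", 11.54),
    (VariableType.PRESCRIPTION, "Furosemide", 5.00),
)

_FIXTURES = {"minimal", "full"}


def load_fixture_rules(name: str) -> RuleModel:
    """Return the transcribed ``minimal`` (13-rule) or ``full`` example model.

    The ``full`` fixture holds the 13 minimal rules plus the four clinical
    rules of the worked patient example — not the complete published
    1,217-rule model, which is not reproducible without the source dataset.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    specs = _MINIMAL_RULES if name == "minimal" else _MINIMAL_RULES + _CLINICAL_RULES
    rules = tuple(
        Rule(antecedent=Item(vt, code), or_value=or_value, p_value=0.0, table=None)
        for vt, code, or_value in specs
    )
    return RuleModel(
        rules=rules,
        p_max=0.0,
        bonferroni=False,
        n_tests=len(rules),
        model_class=name if name == "minimal" else "full",
        decision_boundary=MINIMAL_BOUNDARY if name == "minimal" else FULL_BOUNDARY,
        provenance={"transcribed": True, "source": "published example model"},
    )


def fictional_patient() -> CaseRecord:
    """The worked emergency-department patient: 9 items, outcome unknown.

    Five admission-time demographics (female, Black/African American,
    single, Medicaid, English-speaking) plus four clinical items that
    become available during the stay. The outcome label is a placeholder
    (``survived``); the fixture exists for scoring, not for mining.
    """
    events = [
        (VariableType.ETHNICITY, "Black/African American"),
        (VariableType.GENDER, "Female"),
        (VariableType.INSURANCE_TYPE, "Medicaid"),
        (VariableType.LANGUAGE, "English"),
        (VariableType.MARITAL_STATUS, "Single"),
        (VariableType.DIAGNOSIS, "Acidosis"),
        (VariableType.DIAGNOSIS, "Anuria and oliguria"),
        (VariableType.PRESCRIPTION, "Sodium Bicarbonate"),
        (VariableType.PRESCRIPTION, "Furosemide"),
    ]
    return build_itemset(events, "survived", "fictional-patient")
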