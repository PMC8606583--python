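"""Itemset data model for clinical cases.

A clinical case is represented as a *set* of items — (variable type, code)
pairs such as ``(diagnosis, "Acidosis")`` or ``(gender, "Female")`` — plus a
binary in-hospital mortality outcome. Ten categorical variable types are
supported; five of them (the socio-demographic ones that a patient can report
at admission) form the *minimal* class used by the minimal prediction model,
the other five carry clinical information that accrues during the stay.

Codes are opaque, case-sensitive strings compared by exact match. No
normalisation (trimming, case folding, whitespace collapsing) is applied:
near-duplicate codes such as ``"0.45% Sodium Chloride"`` and
``"0.45 % Sodium Chloride"`` are deliberately kept distinct, because surfacing
such inconsistencies in the mined rules is part of what the method is for.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Tuple, Union


class VariableType(Enum):
    """The ten categorical variable types a case can carry."""

    DIAGNOSIS = "diagnosis"
    ETHNICITY = "ethnicity"
    GENDER = "gender"
    INSURANCE_TYPE = "insurance_type"
    LANGUAGE = "language"
    MARITAL_STATUS = "marital_status"
    PRESCRIPTION = "prescription"
    PROCEDURE = "procedure"
    SERVICE = "service"
    WARD = "ward"

    @property
    def minimal_class(self) -> bool:
        """True for admission-time, patient-reportable demographic types."""
        return self in _MINIMAL_TYPES


_MINIMAL_TYPES = frozenset(
    {
        VariableType.ETHNICITY,
        VariableType.GENDER,
        VariableType.INSURANCE_TYPE,
        VariableType.LANGUAGE,
        VariableType.MARITAL_STATUS,
    }
)

#: The five variable types available at admission (the minimal model class).
MINIMAL_TYPES = _MINIMAL_TYPES


def coerce_variable_type(value: Union[str, VariableType]) -> VariableType:
    """Return the :class:`VariableType` for ``value``, accepting its name.

    Raises ``ValueError`` with the list of valid names on unknown input.
    """
    if isinstance(value, VariableType):
        return value
    try:
        return VariableType(str(value).strip().lower())
    except ValueError:
        valid = ", ".join(sorted(t.value for t in VariableType))
        raise ValueError(
            f"unknown variable type {value!r}; expected one of: {valid}"
        ) from None


_DIED_TOKENS = {"died", "1", "true", "dead", "deceased"}
_SURVIVED_TOKENS = {"survived", "0", "false", "alive"}


def parse_outcome(value: Union[str, int, bool]) -> bool:
    """Parse an outcome label into the boolean ``died``.

    Accepts ``died``/``survived`` (any case) and the synonyms ``1``/``0``.
    """
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    token = str(value).strip().lower()
    if token in _DIED_TOKENS:
        return True
    if token in _SURVIVED_TOKENS:
        return False
    raise ValueError(
        f"unknown outcome {value!r}; expected 'died'/'survived' (or 1/0)"
    )


@dataclass(frozen=True, slots=True)
class Item:
    """One variable-value token, identified by exact (type, code) match."""

    variable_type: VariableType
    code: str

    def __post_init__(self) -> None:
        if not isinstance(self.variable_type, VariableType):
            object.__setattr__(
                self, "variable_type", coerce_variable_type(self.variable_type)
            )


@dataclass(frozen=True, slots=True)
class CaseRecord:
    """One clinical case: a deduplicated item set plus the binary outcome.

    ``died`` is True when the patient died in hospital during this case.
    Empty item sets are allowed — no case is excluded from mining.
    """

    case_id: str
    items: frozenset
    died: bool

    @property
    def outcome(self) -> str:
        return "died" if self.died else "survived"


EventLike = Tuple[Union[str, VariableType], str]


def build_itemset(
    events: Sequence[EventLike] | Iterable[EventLike],
    outcome: Union[str, int, bool],
    case_id: str,
) -> CaseRecord:
    """Transform raw case events into a deduplicated :class:`CaseRecord`.

    ``events`` is any iterable of ``(variable_type, code)`` pairs; repeated
    occurrences of the same variable within the case collapse to a single
    item, and the event order is irrelevant.
    """
    items = frozenset(
        Item(coerce_variable_type(vt), str(code)) for vt, code in events
    )
    return CaseRecord(case_id=str(case_id), items=items, died=parse_outcome(outcome))


def restrict_to_minimal(case: CaseRecord) -> CaseRecord:
    """Return a copy of ``case`` keeping only minimal-class (demographic) items."""
    return CaseRecord(
        case_id=case.case_id,
        items=frozenset(i for i in case.items if i.variable_type.minimal_class),
        died=case.died,
    )
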