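"""Clinical-trial records: data model, JSONL serialization, display transforms.

A :class:`TrialRecord` carries the seven indexed facets used for eligibility
search (age range, sex, cancer type, locations, trial type, phase,
investigational-drug flag) plus three free-text sections (purpose,
procedures, eligibility).  Display helpers produce the simplified title
("Phase II Treatment Trial for Lung Cancer") and the three staged
levels of detail shown to users: level 1 is title + eligibility, level 2
adds the research purpose, level 3 adds the procedure details.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields
from typing import IO, Iterable, Iterator

__all__ = [
    "Phase",
    "TrialType",
    "SexEligibility",
    "TrialRecord",
    "DetailView",
    "parse_corpus",
    "write_corpus",
    "simplify_title",
    "detail_view",
]


class Phase(str, enum.Enum):
    """Clinical-trial phase (I-IV), or UNSPECIFIED when not indexed."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNSPECIFIED = "UNSPECIFIED"


class TrialType(str, enum.Enum):
    TREATMENT = "TREATMENT"
    PREVENTION = "PREVENTION"
    DIAGNOSTIC = "DIAGNOSTIC"
    SCREENING = "SCREENING"
    SUPPORTIVE = "SUPPORTIVE"
    SURVEY = "SURVEY"


class SexEligibility(str, enum.Enum):
    ANY = "ANY"
    FEMALE = "FEMALE"
    MALE = "MALE"


# JSONL key order (also the dataclass field order).
_FIELD_ORDER = (
    "trial_id",
    "full_title",
    "phase",
    "trial_type",
    "cancer_type",
    "min_age",
    "max_age",
    "sex_eligibility",
    "locations",
    "uses_investigational_drug",
    "purpose_text",
    "procedures_text",
    "eligibility_text",
)


@dataclass(frozen=True)
class TrialRecord:
    """One clinical trial: indexed facets plus free-text sections.

    ``locations`` is a frozenset of region codes; the empty set means the
    trial is offered anywhere (unrestricted).
    """

    trial_id: str
    full_title: str
    phase: Phase
    trial_type: TrialType
    cancer_type: str
    min_age: int
    max_age: int
    sex_eligibility: SexEligibility
    locations: frozenset[str] = field(default_factory=frozenset)
    uses_investigational_drug: bool = False
    purpose_text: str = ""
    procedures_text: str = ""
    eligibility_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "trial_type", TrialType(self.trial_type))
        object.__setattr__(
            self, "sex_eligibility", SexEligibility(self.sex_eligibility)
        )
        object.__setattr__(self, "locations", frozenset(self.locations))
        if not self.trial_id:
            raise ValueError("trial_id must be nonempty")
        if not isinstance(self.min_age, int) or not isinstance(self.max_age, int):
            raise ValueError(f"{self.trial_id}: ages must be integers")
        if self.min_age < 0:
            raise ValueError(f"{self.trial_id}: min_age must be >= 0")
        if self.min_age > self.max_age:
            raise ValueError(
                f"{self.trial_id}: min_age ({self.min_age}) exceeds "
                f"max_age ({self.max_age})"
            )

    def to_dict(self) -> dict:
        """Serializable mapping with keys in the canonical JSONL order."""
        d = {}
        for name in _FIELD_ORDER:
            value = getattr(self, name)
            if isinstance(value, enum.Enum):
                value = value.value
            elif isinstance(value, frozenset):
                value = sorted(value)
            d[name] = value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown fields: {sorted(unknown)}")
        return cls(**d)

    def combined_text(self) -> str:
        """Concatenated free text (purpose, procedures, eligibility)."""
        return " ".join(
            (self.purpose_text, self.procedures_text, self.eligibility_text)
        )


@dataclass(frozen=True)
class DetailView:
    """A staged-disclosure view of a trial at one of three levels."""

    level: int
    title: str
    sections: tuple[tuple[str, str], ...]


def simplify_title(record: TrialRecord) -> str:
    """Short display title built from phase, trial type, and cancer type.

    Replaces long protocol titles with e.g. "Phase II Treatment Trial for
    Lung Cancer"; when the phase is unspecified the phase prefix is dropped.
    """
    type_name = record.trial_type.value.title()
    if record.phase is Phase.UNSPECIFIED:
        return f"{type_name} Trial for {record.cancer_type}"
    return f"Phase {record.phase.value} {type_name} Trial for {record.cancer_type}"


_LEVEL_SECTIONS = {
    1: ("eligibility_text",),
    2: ("eligibility_text", "purpose_text"),
    3: ("eligibility_text", "purpose_text", "procedures_text"),
}

_SECTION_NAMES = {
    "eligibility_text": "Eligibility",
    "purpose_text": "Purpose",
    "procedures_text": "Procedures",
}


def detail_view(record: TrialRecord, level: int) -> DetailView:
    """Staged view: level 1 = title + eligibility; 2 adds purpose; 3 adds
    procedures.  Sections at level k are a prefix of those at level k+1."""
    if level not in _LEVEL_SECTIONS:
        raise ValueError(f"detail level must be 1, 2, or 3, got {level!r}")
    sections = tuple(
        (_SECTION_NAMES[f], getattr(record, f)) for f in _LEVEL_SECTIONS[level]
    )
    return DetailView(level=level, title=simplify_title(record), sections=sections)


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\n")


def parse_corpus(stream: str | IO[str] | Iterable[str]) -> list[TrialRecord]:
    """Parse a JSONL corpus (one trial per line); validates all invariants.

    Raises ``ValueError`` naming the offending line on malformed JSON,
    invalid field values, or duplicate trial ids.
    """
    records: list[TrialRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_iter_lines(stream), start=1):
        if not line.strip():
            continue
        try:
            payload = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
        if not isinstance(payload, dict):
            raise ValueError(f"line {lineno}: expected a JSON object")
        try:
            record = TrialRecord.from_dict(payload)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if record.trial_id in seen:
            raise ValueError(f"line {lineno}: duplicate trial_id {record.trial_id!r}")
        seen.add(record.trial_id)
        records.append(record)
    return records


def write_corpus(records: Iterable[TrialRecord], fh: IO[str] | None = None) -> str:
    """Serialize records to JSONL text (and optionally write to ``fh``).

    Keys are emitted in the canonical field order so output is byte-stable.
    """
    text = "".join(json.dumps(r.to_dict()) + "\n" for r in records)
    if fh is not None:
        fh.write(text)
    return text
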