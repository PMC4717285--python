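"""Faceted eligibility filtering, preference ranking, and query relaxation.

Retrieval is fully faceted: a :class:`FacetQuery` sets any subset of the
seven indexed criteria (age, sex, cancer type, location, trial type,
phase, investigational-drug tolerance); unset facets match everything.
Matching trials are then ordered by how closely their inferred subjective
attributes (pain, invasiveness, time burden) agree with the user's stated
preferences.  When a query returns nothing (or the user exhausts the
results), single-facet relaxations are suggested: drop one facet at a
time, in a fixed priority order, and report how many trials that frees.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Sequence

from .id3 import CRITERIA, LEVELS, InferredCriteria
from .records import Phase, SexEligibility, TrialRecord, TrialType

__all__ = [
    "ANYWHERE",
    "FacetQuery",
    "Preferences",
    "Relaxation",
    "RELAXATION_ORDER",
    "matches",
    "filter_trials",
    "rank_trials",
    "suggest_relaxations",
]

#: Sentinel location meaning the user accepts any trial location.
ANYWHERE = "ANYWHERE"

#: Facet names in the order relaxations are tried (least clinically
#: constraining first); configuration, not a property of the data.
RELAXATION_ORDER = (
    "phase",
    "trial_type",
    "location",
    "investigational_drug_ok",
    "cancer_type",
    "sex",
    "age",
)


@dataclass(frozen=True)
class FacetQuery:
    """User search criteria; any facet may be None (= matches everything)."""

    age: int | None = None
    sex: SexEligibility | None = None
    cancer_type: str | None = None
    location: str | None = None  # region code or ANYWHERE
    trial_type: TrialType | None = None
    phase: Phase | None = None
    investigational_drug_ok: bool | None = None

    def set_facets(self) -> list[str]:
        """Names of facets currently set, in field order."""
        return [f.name for f in fields(self) if getattr(self, f.name) is not None]


@dataclass(frozen=True)
class Preferences:
    """Desired level (0-2) per inferred criterion; None = no preference."""

    pain: int | None = None
    invasiveness: int | None = None
    time_burden: int | None = None

    def __post_init__(self) -> None:
        for name in CRITERIA:
            v = getattr(self, name)
            if v is not None and v not in LEVELS:
                raise ValueError(f"{name} preference must be in {LEVELS} or None")

    def set_criteria(self) -> list[str]:
        return [c for c in CRITERIA if getattr(self, c) is not None]


@dataclass(frozen=True)
class Relaxation:
    """One single-facet query relaxation that recovers at least one trial."""

    dropped_facet: str
    relaxed_query: FacetQuery
    hit_count: int


def matches(record: TrialRecord, query: FacetQuery) -> bool:
    """True iff every set facet of ``query`` accepts ``record``.

    Age bounds are inclusive; a trial with no listed locations is offered
    anywhere; ``investigational_drug_ok=False`` excludes trials that use
    an investigational drug (True imposes no constraint).
    """
    if query.age is not None and not (record.min_age <= query.age <= record.max_age):
        return False
    if query.sex is not None:
        if record.sex_eligibility is not SexEligibility.ANY and (
            record.sex_eligibility is not SexEligibility(query.sex)
        ):
            return False
    if query.cancer_type is not None and record.cancer_type != query.cancer_type:
        return False
    if query.location is not None and query.location != ANYWHERE:
        if record.locations and query.location not in record.locations:
            return False
    if query.trial_type is not None and record.trial_type is not TrialType(
        query.trial_type
    ):
        return False
    if query.phase is not None and record.phase is not Phase(query.phase):
        return False
    if query.investigational_drug_ok is False and record.uses_investigational_drug:
        return False
    return True


def filter_trials(
    corpus: Sequence[TrialRecord], query: FacetQuery
) -> list[TrialRecord]:
    """Exactly the records matching ``query``, in corpus order."""
    return [r for r in corpus if matches(r, query)]


def mismatch_score(
    inferred: InferredCriteria, prefs: Preferences
) -> int:
    """Sum over set preferences of |inferred level - desired level|."""
    return sum(
        abs(inferred.level(c) - getattr(prefs, c)) for c in prefs.set_criteria()
    )


def rank_trials(
    trials: Sequence[TrialRecord],
    prefs: Preferences,
    inferred: Mapping[str, InferredCriteria],
) -> list[TrialRecord]:
    """Order trials by preference mismatch (ascending), ties by trial_id.

    With no preference set there is no ranking signal and the input
    (corpus) order is returned unchanged.  Raises ``KeyError`` if a trial
    lacks inferred labels.
    """
    missing = [t.trial_id for t in trials if t.trial_id not in inferred]
    if missing:
        raise KeyError(f"no inferred criteria for trials: {missing}")
    if not prefs.set_criteria():
        return list(trials)
    return sorted(
        trials,
        key=lambda t: (mismatch_score(inferred[t.trial_id], prefs), t.trial_id),
    )


def suggest_relaxations(
    query: FacetQuery, corpus: Sequence[TrialRecord]
) -> list[Relaxation]:
    """Single-facet relaxations that yield at least one hit.

    Each set facet is unset alone, in :data:`RELAXATION_ORDER`; a
    relaxation is reported iff the relaxed query matches >= 1 trial.
    """
    out: list[Relaxation] = []
    set_facets = set(query.set_facets())
    for facet in RELAXATION_ORDER:
        if facet not in set_facets:
            continue
        relaxed = replace(query, **{facet: None})
        hits = len(filter_trials(corpus, relaxed))
        if hits >= 1:
            out.append(
                Relaxation(dropped_facet=facet, relaxed_query=relaxed, hit_count=hits)
            )
    return out
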