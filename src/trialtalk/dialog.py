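"""Augmented-transition-network dialog manager for the search session.

The conversation is system-initiated at the adjacency-pair level: each
turn the agent speaks (template-generated text, optionally with a
display -- a staged trial view, the user's criteria, term definitions,
or a session summary) and offers an ordered menu of utterances; the
user only ever picks one.  A :class:`DialogScript` (loaded from YAML)
defines the states, arcs, templates, and education subnetworks; a set
of built-in state kinds supplies the dynamic behavior a static script
cannot express: interview questions whose menus come from the corpus,
criteria confirmation with revision arcs, search execution, staged
trial presentation with dictionary support, query-refinement offers,
and the summary of viewed/bookmarked trials.

Sessions are fully deterministic given the script, corpus, models, and
choice sequence, so recorded sessions replay byte-for-byte.
"""

from __future__ import annotations

import csv
import io
import json
import string
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .id3 import CRITERIA, InferredCriteria, tokenize
from .records import Phase, SexEligibility, TrialRecord, TrialType, detail_view
from .search import (
    ANYWHERE,
    FacetQuery,
    Preferences,
    filter_trials,
    matches,
    rank_trials,
    suggest_relaxations,
)

__all__ = [
    "Lexicon",
    "DialogScript",
    "UserModel",
    "Turn",
    "Session",
    "DialogEngine",
    "load_script",
    "default_script",
    "default_lexicon",
    "render_template",
    "extract_difficult_terms",
    "session_summary",
    "confirm_criteria",
    "toggle_bookmark",
    "advance",
]


# ---------------------------------------------------------------------------
# lexicon + template + term extraction


class Lexicon:
    """Medical term -> plain-language definition; terms stored lowercase."""

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._terms: dict[str, str] = {}
        for term, definition in (entries or {}).items():
            self.add(term, definition)

    def add(self, term: str, definition: str) -> None:
        key = " ".join(tokenize(term))
        if not key:
            raise ValueError(f"term {term!r} contains no words")
        if key in self._terms:
            raise ValueError(f"duplicate lexicon term {key!r}")
        self._terms[key] = definition

    def __contains__(self, term: str) -> bool:
        return term in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def definition(self, term: str) -> str:
        return self._terms[term]

    @property
    def terms(self) -> dict[str, str]:
        return dict(self._terms)

    @classmethod
    def from_csv(cls, text: str) -> "Lexicon":
        """Load from CSV with columns term,definition (header optional)."""
        lex = cls()
        reader = csv.reader(io.StringIO(text))
        for row in reader:
            if not row or not row[0].strip():
                continue
            if row[0].strip().lower() == "term" and len(lex) == 0:
                continue  # header
            if len(row) < 2:
                raise ValueError(f"lexicon row needs term,definition: {row!r}")
            lex.add(row[0], row[1].strip())
        return lex


def render_template(template: str, context: Mapping[str, Any]) -> str:
    """Replace every ``{slot}`` in ``template`` from ``context``.

    Raises ``KeyError`` naming the slot when a value is missing; no
    markers remain in the output.
    """
    for _, name, _, _ in string.Formatter().parse(template):
        if name is not None and name.split(".")[0].split("[")[0] not in context:
            raise KeyError(f"template slot {name!r} has no value")
    return template.format(**context)


def extract_difficult_terms(
    text: str, lexicon: Lexicon
) -> list[tuple[str, str]]:
    """Lexicon terms occurring in ``text``: case-insensitive longest-match
    scan over tokens, each term reported once in first-occurrence order."""
    if len(lexicon) == 0:
        return []
    tokens = tokenize(text)
    max_len = max(len(t.split()) for t in lexicon.terms)
    found: list[tuple[str, str]] = []
    seen: set[str] = set()
    i = 0
    while i < len(tokens):
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            phrase = " ".join(tokens[i : i + n])
            if phrase in lexicon:
                if phrase not in seen:
                    seen.add(phrase)
                    found.append((phrase, lexicon.definition(phrase)))
                i += n
                break
        else:
            i += 1
    return found


# ---------------------------------------------------------------------------
# script model + loading


@dataclass(frozen=True)
class ChoiceSpec:
    label: str
    goto: str
    enter: str | None = None
    when: str | None = None


@dataclass(frozen=True)
class StateSpec:
    name: str
    kind: str = "plain"
    template: str | None = None
    params: Mapping[str, str] = field(default_factory=dict)
    choices: tuple[ChoiceSpec, ...] = ()


@dataclass(frozen=True)
class DialogScript:
    states: Mapping[str, StateSpec]
    templates: Mapping[str, str]
    start: str
    terminals: frozenset[str]
    subnet_starts: Mapping[str, str] = field(default_factory=dict)
    wrap_up_after: int = 150


#: Per-kind parameter names that must reference existing states.
_KIND_TARGETS = {
    "ask_facet": ("next",),
    "ask_pref": ("next",),
    "confirm": ("accept",),
    "search": ("present", "refine", "summary"),
    "present": ("dictionary", "refine", "summary", "confirm"),
    "dictionary": ("back",),
    "refine": ("search", "confirm", "summary"),
    "summary": ("done",),
}

_KINDS = set(_KIND_TARGETS) | {"plain", "return"}

#: Template slots guaranteed by each dynamic kind (checked at load time
#: so rendering cannot fail mid-session).
_KIND_TEMPLATE_KEYS = ("name", "n", "title", "idx", "total")


def _parse_states(
    raw_states: Mapping, prefix: str = ""
) -> dict[str, StateSpec]:
    states: dict[str, StateSpec] = {}
    for name, spec in raw_states.items():
        qname = prefix + name
        spec = dict(spec or {})
        kind = spec.pop("kind", "plain")
        if kind not in _KINDS:
            raise ValueError(f"state {qname!r}: unknown kind {kind!r}")
        template = spec.pop("template", None)
        raw_choices = spec.pop("choices", [])
        choices = []
        for ch in raw_choices:
            goto = ch.get("goto")
            if goto is None:
                raise ValueError(f"state {qname!r}: choice without goto")
            choices.append(
                ChoiceSpec(
                    label=ch["label"],
                    goto=prefix + goto,
                    enter=ch.get("enter"),
                    when=ch.get("when"),
                )
            )
        params = {
            k: (prefix + v if k in _KIND_TARGETS.get(kind, ()) else v)
            for k, v in spec.items()
        }
        states[qname] = StateSpec(
            name=qname,
            kind=kind,
            template=template,
            params=params,
            choices=tuple(choices),
        )
    return states


def load_script(config: str | Mapping) -> DialogScript:
    """Parse and validate a YAML dialog script.

    Errors name the offending state/template: dangling arc targets,
    undefined templates, missing or unreachable terminals.
    """
    data = yaml.safe_load(config) if isinstance(config, str) else dict(config)
    if not isinstance(data, Mapping):
        raise ValueError("script must be a mapping")
    templates = dict(data.get("templates", {}))
    states = _parse_states(data.get("states", {}))
    sub_entries: dict[str, str] = {}  # subnetwork name -> qualified start
    for sub_name, sub in dict(data.get("subnetworks", {})).items():
        prefix = f"{sub_name}."
        sub_states = _parse_states(sub.get("states", {}), prefix=prefix)
        sub_terminals = [prefix + t for t in sub.get("terminals", [])]
        if not sub_terminals:
            raise ValueError(f"subnetwork {sub_name!r}: no terminal state")
        for t in sub_terminals:
            if t not in sub_states:
                raise ValueError(f"subnetwork {sub_name!r}: unknown terminal {t!r}")
            sub_states[t] = replace(sub_states[t], kind="return")
        sub_start = prefix + sub["start"]
        if sub_start not in sub_states:
            raise ValueError(f"subnetwork {sub_name!r}: unknown start {sub_start!r}")
        sub_entries[sub_name] = sub_start
        templates.update(sub.get("templates", {}))
        states.update(sub_states)

    start = data.get("start")
    if start not in states:
        raise ValueError(f"start state {start!r} is not defined")
    terminals = frozenset(data.get("terminals", []))
    if not terminals:
        raise ValueError("script must declare at least one terminal state")
    for t in terminals:
        if t not in states:
            raise ValueError(f"terminal state {t!r} is not defined")

    edges: dict[str, set[str]] = {name: set() for name in states}
    for st in states.values():
        if st.template is not None and st.template not in templates:
            raise ValueError(
                f"state {st.name!r}: undefined template {st.template!r}"
            )
        for key in _KIND_TARGETS.get(st.kind, ()):
            target = st.params.get(key)
            if target is None:
                raise ValueError(f"state {st.name!r}: missing {key!r} target")
            if target not in states:
                raise ValueError(
                    f"state {st.name!r}: {key} targets undefined state {target!r}"
                )
            edges[st.name].add(target)
        for ch in st.choices:
            if ch.goto not in states:
                raise ValueError(
                    f"state {st.name!r}: arc targets undefined state {ch.goto!r}"
                )
            edges[st.name].add(ch.goto)
            if ch.enter is not None:
                if ch.enter not in sub_entries:
                    raise ValueError(
                        f"state {st.name!r}: unknown subnetwork {ch.enter!r}"
                    )
                edges[st.name].add(sub_entries[ch.enter])
        if (
            st.kind == "plain"
            and st.name not in terminals
            and not st.choices
        ):
            raise ValueError(f"state {st.name!r}: non-terminal state has no arcs")
    # confirm/refine can jump back to any interview state
    ask_states = {
        s.name for s in states.values() if s.kind in ("ask_facet", "ask_pref")
    }
    for st in states.values():
        if st.kind in ("confirm",):
            edges[st.name] |= ask_states
        if st.kind == "return":
            # a return state resumes wherever its caller pointed; treat it
            # as connected to every state a subnetwork entry resumes at
            for other in states.values():
                for ch in other.choices:
                    if ch.enter is not None:
                        edges[st.name].add(ch.goto)
    reachable = {start}
    frontier = [start]
    while frontier:
        cur = frontier.pop()
        for nxt in edges.get(cur, ()):
            if nxt not in reachable:
                reachable.add(nxt)
                frontier.append(nxt)
    for t in terminals:
        if t not in reachable:
            raise ValueError(f"terminal state {t!r} is unreachable from start")

    settings = dict(data.get("settings", {}))
    return DialogScript(
        states=states,
        templates=templates,
        start=start,
        terminals=terminals,
        subnet_starts=sub_entries,
        wrap_up_after=int(settings.get("wrap_up_after", 150)),
    )


def default_script() -> DialogScript:
    """The shipped session flow: tutorial -> interview -> confirm ->
    search -> staged presentation -> refine -> summary -> farewell."""
    text = (
        resources.files("trialtalk.data")
        .joinpath("default_script.yaml")
        .read_text()
    )
    return load_script(text)


def default_lexicon() -> Lexicon:
    text = resources.files("trialtalk.data").joinpath("lexicon.csv").read_text()
    return Lexicon.from_csv(text)


# ---------------------------------------------------------------------------
# session state


@dataclass
class UserModel:
    """What the interview has collected so far; only menu-offered values
    are ever stored (the display name is the one free-text field)."""

    name: str = "there"
    query: FacetQuery = field(default_factory=FacetQuery)
    prefs: Preferences = field(default_factory=Preferences)
    tutorials_seen: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Arc:
    label: str
    goto: str
    action: str | None = None
    payload: Mapping[str, Any] = field(default_factory=dict)
    enter: str | None = None


@dataclass(frozen=True)
class Turn:
    """One agent turn: utterance, optional display, ordered choice menu."""

    state: str
    utterance: str
    display: Any
    choices: tuple[str, ...]
    arcs: tuple[Arc, ...] = ()

    def to_transcript_entry(self, chosen: int | None = None) -> dict:
        entry = {
            "state": self.state,
            "utterance": self.utterance,
            "display": self.display,
            "choices": list(self.choices),
        }
        if chosen is not None:
            entry["chosen"] = chosen
        return entry


@dataclass
class Session:
    """Running session: user model, control state, results, history."""

    engine: "DialogEngine"
    user: UserModel
    state: str
    stack: list[str] = field(default_factory=list)
    results: list[str] = field(default_factory=list)
    result_index: int = 0
    current_level: int = 1
    trials_viewed: list[str] = field(default_factory=list)
    bookmarks: list[str] = field(default_factory=list)
    view_log: list[tuple[str, int]] = field(default_factory=list)
    transcript: list[dict] = field(default_factory=list)
    pending_return: str | None = None

    @property
    def done(self) -> bool:
        return self.state in self.engine.script.terminals

    def current_trial_id(self) -> str | None:
        if 0 <= self.result_index < len(self.results):
            return self.results[self.result_index]
        return None


def session_summary(session: Session) -> list[tuple[str, bool]]:
    """Trials viewed this session, in view order, flagged bookmarked."""
    marked = set(session.bookmarks)
    return [(tid, tid in marked) for tid in session.trials_viewed]


def toggle_bookmark(session: Session, trial_id: str) -> None:
    """Bookmark/unbookmark a viewed trial (bookmarks stay a subset of
    the trials viewed)."""
    if trial_id not in session.trials_viewed:
        raise ValueError(f"cannot bookmark unviewed trial {trial_id!r}")
    if trial_id in session.bookmarks:
        session.bookmarks.remove(trial_id)
    else:
        session.bookmarks.append(trial_id)


_FACET_LABELS = {
    "age": "age",
    "sex": "sex",
    "cancer_type": "cancer type",
    "location": "location",
    "trial_type": "trial type",
    "phase": "phase",
    "investigational_drug_ok": "investigational drug",
}

_PREF_LABELS = {
    "pain": "pain",
    "invasiveness": "invasiveness",
    "time_burden": "time commitment",
}

_LEVEL_WORDS = {0: "low", 1: "medium", 2: "high"}


def _facet_display(facet: str, value: Any) -> str:
    if isinstance(value, (Phase, TrialType, SexEligibility)):
        return value.value.title()
    if value is True:
        return "OK"
    if value is False:
        return "Avoid"
    return str(value)


def confirm_criteria(session: Session) -> tuple[dict, list[str]]:
    """The criteria display plus the revision menu: one "Change X" per
    set facet/preference, then the accepting choice."""
    query, prefs = session.user.query, session.user.prefs
    display = {
        "type": "criteria",
        "facets": [
            [f, _facet_display(f, getattr(query, f))] for f in query.set_facets()
        ],
        "preferences": [
            [c, _LEVEL_WORDS[getattr(prefs, c)]] for c in prefs.set_criteria()
        ],
    }
    choices = [
        f"Change the {_FACET_LABELS[f]}." for f in query.set_facets()
    ] + [
        f"Change the {_PREF_LABELS[c]} preference." for c in prefs.set_criteria()
    ]
    choices.append("That all looks right.")
    return display, choices


# ---------------------------------------------------------------------------
# engine


class DialogEngine:
    """Executes a dialog script against a corpus with inferred criteria.

    Parameters
    ----------
    script : DialogScript
    corpus : sequence of TrialRecord
    inferred : mapping trial_id -> InferredCriteria
        Subjective labels used for ranking (from the ID3 models).
    lexicon : Lexicon, optional
        Medical-term dictionary for difficult-term extraction.
    """

    def __init__(
        self,
        script: DialogScript,
        corpus: Sequence[TrialRecord],
        inferred: Mapping[str, InferredCriteria],
        lexicon: Lexicon | None = None,
    ):
        self.script = script
        self.corpus = list(corpus)
        self.inferred = dict(inferred)
        self.lexicon = lexicon if lexicon is not None else Lexicon()
        self.by_id = {r.trial_id: r for r in self.corpus}
        missing = [t for t in self.by_id if t not in self.inferred]
        if missing:
            raise ValueError(f"no inferred criteria for trials: {missing[:5]}")
        self._facet_states = {
            st.params["facet"]: st.name
            for st in script.states.values()
            if st.kind == "ask_facet"
        }
        self._pref_states = {
            st.params["criterion"]: st.name
            for st in script.states.values()
            if st.kind == "ask_pref"
        }
        self._summary_state = next(
            (s.name for s in script.states.values() if s.kind == "summary"), None
        )

    # -- session lifecycle ---------------------------------------------------

    def new_session(self, name: str = "there") -> Session:
        return Session(engine=self, user=UserModel(name=name), state=self.script.start)

    # -- turn construction (pure: no session mutation) -----------------------

    def current_turn(self, session: Session) -> Turn:
        state = self.script.states[session.state]
        if session.state in self.script.terminals:
            return Turn(
                state=state.name,
                utterance=self._render(state, session, {}),
                display=None,
                choices=(),
            )
        if (
            len(session.transcript) >= self.script.wrap_up_after
            and self._summary_state is not None
            and state.kind not in ("summary",)
            and session.state != self._summary_state
        ):
            arcs = (
                Arc(label="Let's wrap up for today.", goto=self._summary_state),
            )
            return Turn(
                state=state.name,
                utterance="We have covered a lot today. Let's wrap up.",
                display=None,
                choices=tuple(a.label for a in arcs),
                arcs=arcs,
            )
        builder = getattr(self, f"_turn_{state.kind}")
        turn = builder(state, session)
        if not turn.arcs:
            raise RuntimeError(f"state {state.name!r} produced no choices")
        return turn

    def _render(
        self, state: StateSpec, session: Session, extra: Mapping[str, Any]
    ) -> str:
        template = self.script.templates[state.template]
        context = {"name": session.user.name, **extra}
        return render_template(template, context)

    def _guard_ok(self, when: str | None, session: Session) -> bool:
        if when is None:
            return True
        predicates = {
            "has_results": len(session.results) > 0,
            "no_results": len(session.results) == 0,
            "more_trials": session.result_index + 1 < len(session.results),
        }
        if when not in predicates:
            raise ValueError(f"unknown guard {when!r}")
        return predicates[when]

    def _turn_plain(self, state: StateSpec, session: Session) -> Turn:
        arcs = tuple(
            Arc(label=c.label, goto=c.goto, enter=c.enter)
            for c in state.choices
            if self._guard_ok(c.when, session)
        )
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=None,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    def _turn_return(self, state: StateSpec, session: Session) -> Turn:
        raise RuntimeError(
            f"return state {state.name!r} should never be displayed"
        )

    def _facet_options(self, facet: str) -> list[tuple[str, Any]]:
        if facet == "cancer_type":
            values = sorted({r.cancer_type for r in self.corpus})
            return [(v, v) for v in values] + [("Any kind of cancer.", None)]
        if facet == "age":
            return [(str(a), a) for a in range(20, 100, 10)] + [
                ("I'd rather not say.", None)
            ]
        if facet == "sex":
            return [
                ("Female.", SexEligibility.FEMALE),
                ("Male.", SexEligibility.MALE),
                ("It doesn't matter.", None),
            ]
        if facet == "location":
            codes = sorted({c for r in self.corpus for c in r.locations})
            return [(c.title() + ".", c) for c in codes] + [
                ("It can be anywhere.", ANYWHERE)
            ]
        if facet == "trial_type":
            return [(t.value.title() + ".", t) for t in TrialType] + [
                ("Any type is fine.", None)
            ]
        if facet == "phase":
            return [
                (f"Phase {p.value}.", p)
                for p in (Phase.I, Phase.II, Phase.III, Phase.IV)
            ] + [("Any phase is fine.", None)]
        if facet == "investigational_drug_ok":
            return [
                ("Yes, that's fine.", True),
                ("No, I'd rather avoid that.", False),
                ("I'm not sure.", None),
            ]
        raise ValueError(f"unknown facet {facet!r}")

    def _turn_ask_facet(self, state: StateSpec, session: Session) -> Turn:
        facet = state.params["facet"]
        goto = session.pending_return or state.params["next"]
        arcs = tuple(
            Arc(
                label=label,
                goto=goto,
                action="set_facet",
                payload={"facet": facet, "value": value},
            )
            for label, value in self._facet_options(facet)
        )
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=None,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    def _turn_ask_pref(self, state: StateSpec, session: Session) -> Turn:
        criterion = state.params["criterion"]
        goto = session.pending_return or state.params["next"]
        options = [
            ("As low as possible.", 0),
            ("Medium is fine.", 1),
            ("High is fine.", 2),
            ("No preference.", None),
        ]
        arcs = tuple(
            Arc(
                label=label,
                goto=goto,
                action="set_pref",
                payload={"criterion": criterion, "value": value},
            )
            for label, value in options
        )
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=None,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    def _turn_confirm(self, state: StateSpec, session: Session) -> Turn:
        display, labels = confirm_criteria(session)
        query, prefs = session.user.query, session.user.prefs
        arcs: list[Arc] = []
        for facet in query.set_facets():
            arcs.append(
                Arc(
                    label=f"Change the {_FACET_LABELS[facet]}.",
                    goto=self._facet_states[facet],
                    action="set_pending_return",
                    payload={"state": state.name},
                )
            )
        for criterion in prefs.set_criteria():
            arcs.append(
                Arc(
                    label=f"Change the {_PREF_LABELS[criterion]} preference.",
                    goto=self._pref_states[criterion],
                    action="set_pending_return",
                    payload={"state": state.name},
                )
            )
        arcs.append(Arc(label="That all looks right.", goto=state.params["accept"]))
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=display,
            choices=tuple(labels),
            arcs=tuple(arcs),
        )

    def _turn_search(self, state: StateSpec, session: Session) -> Turn:
        n = len(session.results)
        if n > 0:
            utterance = self._render(state, session, {"n": n})
            arcs = (
                Arc(label="Show me the first trial.", goto=state.params["present"]),
                Arc(label="I'm done for now.", goto=state.params["summary"]),
            )
        else:
            template_none = state.params.get("template_none")
            utterance = render_template(
                self.script.templates[template_none]
                if template_none
                else "I could not find any trials matching all of your criteria.",
                {"name": session.user.name},
            )
            arcs = (
                Arc(
                    label="What could we change to find some?",
                    goto=state.params["refine"],
                ),
                Arc(label="I'm done for now.", goto=state.params["summary"]),
            )
        return Turn(
            state=state.name,
            utterance=utterance,
            display=None,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    def _present_view(self, session: Session):
        tid = session.current_trial_id()
        record = self.by_id[tid]
        return record, detail_view(record, session.current_level)

    def _turn_present(self, state: StateSpec, session: Session) -> Turn:
        record, dv = self._present_view(session)
        section_text = " ".join(text for _, text in dv.sections)
        terms = extract_difficult_terms(section_text, self.lexicon)
        display = {
            "type": "detail",
            "trial_id": record.trial_id,
            "level": dv.level,
            "title": dv.title,
            "sections": [[name, text] for name, text in dv.sections],
        }
        utterance = self._render(
            state,
            session,
            {
                "idx": session.result_index + 1,
                "total": len(session.results),
                "title": dv.title,
            },
        )
        arcs: list[Arc] = []
        if session.current_level < 3:
            arcs.append(
                Arc(
                    label="Tell me more about this trial.",
                    goto=state.name,
                    action="level_up",
                )
            )
        if terms:
            arcs.append(
                Arc(
                    label="What do some of those medical words mean?",
                    goto=state.params["dictionary"],
                )
            )
        if record.trial_id in session.bookmarks:
            arcs.append(
                Arc(
                    label="Remove the bookmark from this trial.",
                    goto=state.name,
                    action="toggle_bookmark",
                )
            )
        else:
            arcs.append(
                Arc(
                    label="Bookmark this trial for later.",
                    goto=state.name,
                    action="toggle_bookmark",
                )
            )
        if session.result_index + 1 < len(session.results):
            arcs.append(
                Arc(
                    label="Show me the next trial.",
                    goto=state.name,
                    action="next_trial",
                )
            )
        else:
            arcs.append(
                Arc(
                    label="That was the last one. What else could we try?",
                    goto=state.params["refine"],
                )
            )
        arcs.append(
            Arc(
                label="Show me a summary of what we've seen.",
                goto=state.params["summary"],
            )
        )
        arcs.append(
            Arc(
                label="Let me change my search criteria.",
                goto=state.params["confirm"],
            )
        )
        return Turn(
            state=state.name,
            utterance=utterance,
            display=display,
            choices=tuple(a.label for a in arcs),
            arcs=tuple(arcs),
        )

    def _turn_dictionary(self, state: StateSpec, session: Session) -> Turn:
        _, dv = self._present_view(session)
        section_text = " ".join(text for _, text in dv.sections)
        terms = extract_difficult_terms(section_text, self.lexicon)
        display = {
            "type": "definitions",
            "terms": [[t, d] for t, d in terms],
        }
        arcs = (Arc(label="Thanks, that helps.", goto=state.params["back"]),)
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=display,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    def _turn_refine(self, state: StateSpec, session: Session) -> Turn:
        relaxations = suggest_relaxations(session.user.query, self.corpus)
        arcs: list[Arc] = []
        for rel in relaxations:
            arcs.append(
                Arc(
                    label=(
                        f"Search without the {_FACET_LABELS[rel.dropped_facet]} "
                        f"requirement ({rel.hit_count} trials)."
                    ),
                    goto=state.params["search"],
                    action="set_facet",
                    payload={"facet": rel.dropped_facet, "value": None},
                )
            )
        arcs.append(
            Arc(
                label="Let me revise my answers instead.",
                goto=state.params["confirm"],
            )
        )
        arcs.append(Arc(label="I'm done for now.", goto=state.params["summary"]))
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=None,
            choices=tuple(a.label for a in arcs),
            arcs=tuple(arcs),
        )

    def _turn_summary(self, state: StateSpec, session: Session) -> Turn:
        display = {
            "type": "summary",
            "trials": [
                [tid, bookmarked] for tid, bookmarked in session_summary(session)
            ],
        }
        arcs = (Arc(label="That's everything. Goodbye!", goto=state.params["done"]),)
        return Turn(
            state=state.name,
            utterance=self._render(state, session, {}),
            display=display,
            choices=tuple(a.label for a in arcs),
            arcs=arcs,
        )

    # -- transition ----------------------------------------------------------

    def advance(self, session: Session, choice_index: int) -> Turn:
        """Execute the chosen arc of the current turn and return the next
        turn.  Deterministic given script, corpus, models, and prior
        choices."""
        if session.done:
            raise ValueError("session has ended; cannot advance a terminal state")
        turn = self.current_turn(session)
        if not (0 <= choice_index < len(turn.arcs)):
            raise IndexError(
                f"choice index {choice_index} out of range "
                f"(state {session.state!r} offers {len(turn.arcs)} choices)"
            )
        arc = turn.arcs[choice_index]
        session.transcript.append(turn.to_transcript_entry(chosen=choice_index))
        self._apply_action(session, arc)
        state_kind = self.script.states[session.state].kind
        if state_kind in ("ask_facet", "ask_pref") and session.pending_return:
            if arc.goto == session.pending_return:
                session.pending_return = None
        if arc.enter is not None:
            session.stack.append(arc.goto)
            session.state = self.script.subnet_starts[arc.enter]
            session.user.tutorials_seen.add(arc.enter)
        else:
            session.state = arc.goto
        # unwind subnetwork returns
        while self.script.states[session.state].kind == "return":
            session.state = session.stack.pop()
        self._entry_effects(session)
        return self.current_turn(session)

    def _apply_action(self, session: Session, arc: Arc) -> None:
        if arc.action is None:
            return
        if arc.action == "set_facet":
            session.user.query = replace(
                session.user.query, **{arc.payload["facet"]: arc.payload["value"]}
            )
        elif arc.action == "set_pref":
            session.user.prefs = replace(
                session.user.prefs,
                **{arc.payload["criterion"]: arc.payload["value"]},
            )
        elif arc.action == "set_pending_return":
            session.pending_return = arc.payload["state"]
        elif arc.action == "level_up":
            session.current_level = min(3, session.current_level + 1)
        elif arc.action == "toggle_bookmark":
            toggle_bookmark(session, session.current_trial_id())
        elif arc.action == "next_trial":
            session.result_index += 1
            session.current_level = 1
        else:
            raise ValueError(f"unknown action {arc.action!r}")

    def _entry_effects(self, session: Session) -> None:
        kind = self.script.states[session.state].kind
        if kind == "search":
            hits = filter_trials(self.corpus, session.user.query)
            ranked = rank_trials(hits, session.user.prefs, self.inferred)
            session.results = [r.trial_id for r in ranked]
            session.result_index = 0
            session.current_level = 1
        elif kind == "present":
            tid = session.current_trial_id()
            if tid is None:
                raise RuntimeError("present state entered with no results")
            record = self.by_id[tid]
            if not matches(record, session.user.query):
                raise RuntimeError(
                    f"presented trial {tid} no longer matches the confirmed query"
                )
            if tid not in session.trials_viewed:
                session.trials_viewed.append(tid)
            entry = (tid, session.current_level)
            if not session.view_log or session.view_log[-1] != entry:
                session.view_log.append(entry)

    # -- drivers -------------------------------------------------------------

    def replay(self, choices: Iterable[int], name: str = "there") -> Session:
        """Run a recorded choice sequence; returns the finished session."""
        session = self.new_session(name=name)
        for idx in choices:
            self.advance(session, idx)
        return session

    def random_walk(
        self, seed: int, max_turns: int = 500, name: str = "there"
    ) -> Session:
        """Walk the script choosing uniformly among offered choices."""
        rng = np.random.default_rng(seed)
        session = self.new_session(name=name)
        for _ in range(max_turns):
            if session.done:
                break
            turn = self.current_turn(session)
            self.advance(session, int(rng.integers(0, len(turn.arcs))))
        return session


def advance(session: Session, choice_index: int) -> Turn:
    """Module-level convenience: advance a session one chosen arc."""
    return session.engine.advance(session, choice_index)


def transcript_jsonl(session: Session) -> str:
    """Serialize the transcript as JSONL (one turn per line)."""
    return "".join(json.dumps(e) + "\n" for e in session.transcript)
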