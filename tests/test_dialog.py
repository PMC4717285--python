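"""Dialog engine: script loading, turn taking, session invariants."""

import json

import pytest

from trialtalk import dialog, synth
from trialtalk.dialog import (
    DialogEngine,
    Lexicon,
    confirm_criteria,
    default_lexicon,
    default_script,
    extract_difficult_terms,
    load_script,
    render_template,
    session_summary,
    toggle_bookmark,
    transcript_jsonl,
)
from trialtalk.search import matches

MINIMAL_SCRIPT = """
start: greet
terminals: [end]
templates:
  greet: "Hello {name}."
  bye: "Goodbye."
states:
  greet:
    kind: plain
    template: greet
    choices:
      - label: "Bye."
        goto: end
  end:
    kind: plain
    template: bye
"""


class TestRenderTemplate:
    def test_simple_slot(self):
        assert render_template("Hello {name}.", {"name": "Rosa"}) == "Hello Rosa."

    def test_zero_value(self):
        assert render_template("I found {n} trials.", {"n": 0}) == "I found 0 trials."

    def test_missing_slot_named_in_error(self):
        with pytest.raises(KeyError, match="n"):
            render_template("I found {n} trials.", {"name": "Rosa"})


class TestLexicon:
    def test_from_csv_and_lookup(self):
        lex = Lexicon.from_csv("term,definition\nPlacebo,An inactive treatment.\n")
        assert "placebo" in lex
        assert lex.definition("placebo") == "An inactive treatment."

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Lexicon({"placebo": "a"}).add("Placebo", "b")


class TestExtractDifficultTerms:
    def test_empty_lexicon(self):
        assert extract_difficult_terms("any text", Lexicon()) == []

    def test_scan_in_first_occurrence_order(self):
        lex = Lexicon({"placebo": "sugar pill", "metastatic": "spread"})
        out = extract_difficult_terms(
            "a placebo-controlled study of metastatic disease", lex
        )
        assert [t for t, _ in out] == ["placebo", "metastatic"]

    def test_term_occurring_twice_listed_once(self):
        lex = Lexicon({"biopsy": "tissue sample"})
        out = extract_difficult_terms("biopsy then another biopsy", lex)
        assert out == [("biopsy", "tissue sample")]

    def test_longest_match_wins_for_multiword_terms(self):
        lex = Lexicon({"consent": "agreement", "informed consent": "the talk"})
        out = extract_difficult_terms("sign the Informed Consent form", lex)
        assert [t for t, _ in out] == ["informed consent"]


class TestLoadScript:
    def test_minimal_two_state_script(self):
        script = load_script(MINIMAL_SCRIPT)
        assert script.start == "greet"
        assert script.terminals == frozenset({"end"})

    def test_dangling_arc_target_rejected(self):
        bad = MINIMAL_SCRIPT.replace("goto: end", "goto: nowhere")
        with pytest.raises(ValueError, match="nowhere"):
            load_script(bad)

    def test_undefined_template_rejected(self):
        bad = MINIMAL_SCRIPT.replace("template: bye", "template: missing")
        with pytest.raises(ValueError, match="missing"):
            load_script(bad)

    def test_unreachable_terminal_rejected(self):
        import yaml

        data = yaml.safe_load(MINIMAL_SCRIPT)
        data["states"]["orphan_end"] = {"kind": "plain", "template": "bye"}
        data["terminals"] = ["end", "orphan_end"]
        with pytest.raises(ValueError, match="orphan_end"):
            load_script(data)

    def test_shipped_script_structure(self):
        script = default_script()
        expected = {
            "greet", "tutorial_offer", "confirm", "search", "present",
            "dictionary", "refine", "summary", "farewell",
        }
        assert expected <= set(script.states)
        interview = {
            s.name for s in script.states.values()
            if s.kind in ("ask_facet", "ask_pref")
        }
        assert len(interview) == 10  # 7 facets + 3 preferences
        assert "trial_basics.what" in script.states


class TestAdvance:
    def test_greeting_leads_to_interview(self, engine):
        session = engine.new_session(name="Rosa")
        turn = engine.current_turn(session)
        assert "Rosa" in turn.utterance
        turn = engine.advance(session, 0)  # let's get started
        assert session.state == "tutorial_offer"
        turn = engine.advance(session, 1)  # skip the tutorial
        assert session.state == "ask_cancer"
        assert "Breast Cancer" in turn.choices

    def test_choice_sets_facet_and_moves_on(self, engine):
        session = engine.new_session()
        engine.advance(session, 0)
        turn = engine.advance(session, 1)
        idx = turn.choices.index("Breast Cancer")
        engine.advance(session, idx)
        assert session.user.query.cancer_type == "Breast Cancer"
        assert session.state == "ask_age"

    def test_out_of_range_choice_rejected(self, engine):
        session = engine.new_session()
        with pytest.raises(IndexError):
            engine.advance(session, 99)

    def test_advance_on_terminal_rejected(self, engine):
        session = engine.random_walk(seed=0)
        assert session.done
        with pytest.raises(ValueError, match="terminal"):
            engine.advance(session, 0)

    def test_tutorial_subnetwork_enters_and_returns(self, engine):
        session = engine.new_session()
        engine.advance(session, 0)
        engine.advance(session, 0)  # yes, explain trials
        assert session.state == "trial_basics.what"
        engine.advance(session, 0)
        engine.advance(session, 0)
        engine.advance(session, 0)  # got it -> return state pops back
        assert session.state == "ask_cancer"
        assert session.stack == []


class TestSessionBookkeeping:
    def test_fresh_session_summary_empty(self, engine):
        assert session_summary(engine.new_session()) == []

    def test_viewed_and_bookmarked_flags(self, engine):
        session = engine.new_session()
        session.trials_viewed.extend(["A", "B", "C"])
        toggle_bookmark(session, "B")
        assert session_summary(session) == [("A", False), ("B", True), ("C", False)]
        toggle_bookmark(session, "B")
        assert session_summary(session) == [("A", False), ("B", False), ("C", False)]

    def test_unviewed_trial_cannot_be_bookmarked(self, engine):
        with pytest.raises(ValueError):
            toggle_bookmark(engine.new_session(), "NCT0000000")

    def test_confirm_criteria_cardinality(self, engine):
        from dataclasses import replace

        session = engine.new_session()
        session.user.query = replace(
            session.user.query, cancer_type="Breast Cancer", age=70
        )
        display, choices = confirm_criteria(session)
        assert len(display["facets"]) == 2
        assert sum(c.startswith("Change") for c in choices) == 2
        assert choices[-1] == "That all looks right."

    def test_confirm_criteria_degenerate_accept_only(self, engine):
        display, choices = confirm_criteria(engine.new_session())
        assert display["facets"] == [] and display["preferences"] == []
        assert choices == ["That all looks right."]

    def test_revise_loops_back_to_confirm(self, engine):
        # skip every interview question (the location question has no
        # skip: "anywhere" is itself a value, so location ends up set)
        session = engine.new_session()
        engine.advance(session, 0)
        engine.advance(session, 1)
        while session.state != "confirm":
            turn = engine.current_turn(session)
            engine.advance(session, len(turn.choices) - 1)
        turn = engine.current_turn(session)
        assert turn.choices == ("Change the location.", "That all looks right.")
        # revising jumps to the location question and returns to confirm
        engine.advance(session, 0)
        assert session.state == "ask_location"
        turn = engine.current_turn(session)
        engine.advance(session, 0)  # pick the first region
        assert session.state == "confirm"
        assert session.user.query.location not in (None, "ANYWHERE")


class TestSessionProperties:
    def test_random_walks_terminate(self, engine):
        for seed in range(25):
            session = engine.random_walk(seed, max_turns=500)
            assert session.done

    def test_replay_reproduces_transcript_byte_for_byte(self, engine):
        recorded = engine.random_walk(seed=7)
        choices = [entry["chosen"] for entry in recorded.transcript]
        replayed = engine.replay(choices)
        assert transcript_jsonl(recorded) == transcript_jsonl(replayed)

    def test_presented_trials_satisfy_current_query(self, engine):
        for seed in (1, 5, 9):
            recorded = engine.random_walk(seed)
            session = engine.new_session()
            for entry in recorded.transcript:
                engine.advance(session, entry["chosen"])
                if not session.done:
                    turn = engine.current_turn(session)
                    if isinstance(turn.display, dict) and turn.display.get(
                        "type"
                    ) == "detail":
                        record = engine.by_id[turn.display["trial_id"]]
                        assert matches(record, session.user.query)

    def test_staged_disclosure(self, engine):
        for seed in range(15):
            session = engine.random_walk(seed)
            deepest = {}
            for tid, level in session.view_log:
                assert level <= deepest.get(tid, 0) + 1
                deepest[tid] = max(deepest.get(tid, 0), level)

    def test_bookmarks_subset_of_viewed(self, engine):
        for seed in range(15):
            session = engine.random_walk(seed)
            assert set(session.bookmarks) <= set(session.trials_viewed)

    def test_transcript_serializes_to_jsonl(self, engine):
        session = engine.random_walk(seed=2)
        lines = transcript_jsonl(session).splitlines()
        assert len(lines) == len(session.transcript)
        assert all(isinstance(json.loads(l), dict) for l in lines)
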