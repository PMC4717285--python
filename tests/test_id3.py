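"""ID3 word-occurrence trees: entropy, gain, induction, classification."""

import numpy as np
import pytest
from sklearn.base import clone

from trialtalk import synth
from trialtalk.id3 import (
    CRITERIA,
    HIGH,
    LOW,
    MEDIUM,
    Id3Classifier,
    InferredCriteria,
    LabeledExample,
    Leaf,
    Node,
    classify,
    entropy,
    featurize,
    infer_criteria,
    information_gain,
    tokenize,
    train_id3,
    tree_from_dict,
    tree_to_dict,
)


class TestTokenizerAndFeatures:
    def test_whole_token_membership(self):
        fv = featurize("Biopsy required; weekly infusion.", {"biopsy", "surgery"})
        assert fv == {"biopsy": True, "surgery": False}

    def test_empty_text_all_false(self):
        assert featurize("", {"a", "b"}) == {"a": False, "b": False}

    def test_hyphen_splits_tokens(self):
        assert featurize("pre-biopsy", {"biopsy"}) == {"biopsy": True}
        assert tokenize("pre-biopsy check-UP 3mg") == ["pre", "biopsy", "check", "up", "mg"]

    def test_substring_is_not_a_token(self):
        assert featurize("biopsies", {"biopsy"}) == {"biopsy": False}

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            featurize("text", set())


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1), 1.0), ((4, 0), 0.0), ((3, 1), 0.8113), ((2, 2, 2), np.log2(3))],
    )
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))

    def test_bounds_for_three_levels(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(0, 10, size=3)
            if counts.sum() == 0:
                continue
            h = entropy(tuple(counts))
            assert 0.0 <= h <= np.log2(3) + 1e-12
            assert (h == 0.0) == ((counts > 0).sum() == 1)


def _fv(**kw):
    return kw


class TestInformationGain:
    def test_perfect_split_of_uniform_pair(self):
        ex = [
            (_fv(w=True), HIGH),
            (_fv(w=True), HIGH),
            (_fv(w=False), LOW),
            (_fv(w=False), LOW),
        ]
        assert information_gain(ex, "w") == pytest.approx(1.0)

    def test_word_on_all_examples_no_gain(self):
        ex = [(_fv(w=True), HIGH), (_fv(w=True), LOW)]
        assert information_gain(ex, "w") == pytest.approx(0.0)

    def test_partial_split(self):
        # 6 examples (3 H, 3 L); word present on 3 H and 1 L:
        # 1 - (4/6)*0.8113 - (2/6)*0 = 0.4591
        ex = (
            [(_fv(w=True), HIGH)] * 3
            + [(_fv(w=True), LOW)]
            + [(_fv(w=False), LOW)] * 2
        )
        assert information_gain(ex, "w") == pytest.approx(0.4591, abs=1e-4)

    def test_gain_nonnegative_and_bounded_by_parent(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            ex = [
                ({"w": bool(rng.integers(2))}, int(rng.integers(3)))
                for _ in range(n)
            ]
            parent = entropy(np.bincount([l for _, l in ex], minlength=3))
            g = information_gain(ex, "w")
            assert -1e-12 <= g <= parent + 1e-12


class TestTrainId3:
    def test_single_rule_recovered(self):
        ex = [
            LabeledExample("a biopsy is required", HIGH),
            LabeledExample("this biopsy hurts", HIGH),
            LabeledExample("just a study survey", LOW),
            LabeledExample("reading study material", LOW),
        ]
        tree = train_id3(ex, vocabulary={"biopsy", "study"})
        assert tree == Node("biopsy", Leaf(HIGH), Leaf(LOW))

    def test_pure_examples_give_leaf(self):
        ex = [LabeledExample("alpha beta", MEDIUM), LabeledExample("gamma", MEDIUM)]
        assert train_id3(ex, vocabulary={"alpha", "beta", "gamma"}) == Leaf(MEDIUM)

    def test_empty_vocabulary_majority_leaf(self):
        ex = [
            LabeledExample("x", LOW),
            LabeledExample("y", HIGH),
            LabeledExample("z", HIGH),
        ]
        assert train_id3(ex, vocabulary=[]) == Leaf(HIGH)

    def test_majority_tie_breaks_to_lowest_label(self):
        ex = [LabeledExample("x", LOW), LabeledExample("y", HIGH)]
        assert train_id3(ex, vocabulary=["absent"]) == Leaf(LOW)

    def test_equal_gain_tie_breaks_lexicographically(self):
        # "alpha" and "zeta" both split perfectly; alpha must be chosen
        ex = [
            LabeledExample("alpha zeta", HIGH),
            LabeledExample("alpha zeta", HIGH),
            LabeledExample("nothing", LOW),
        ]
        tree = train_id3(ex, vocabulary={"alpha", "zeta"})
        assert isinstance(tree, Node) and tree.word == "alpha"

    def test_two_informative_words_hand_checked(self):
        # One word per label, each splitting its own level off perfectly.
        # Hand-computed root gains: every word yields
        # log2(3) - (4/6)*1 = 0.918 bits, a three-way tie, so the
        # lexicographically smallest word "infusion" is the root; its
        # absent branch is split exactly by "surgery".
        ex = [
            LabeledExample("surgery planned", HIGH),
            LabeledExample("surgery and checkup", HIGH),
            LabeledExample("weekly infusion", MEDIUM),
            LabeledExample("infusion visits", MEDIUM),
            LabeledExample("survey only", LOW),
            LabeledExample("reading survey", LOW),
        ]
        tree = train_id3(ex, vocabulary={"surgery", "infusion", "survey"})
        assert tree == Node(
            "infusion", Leaf(MEDIUM), Node("surgery", Leaf(HIGH), Leaf(LOW))
        )
        for e in ex:
            assert classify(tree, e.text) == e.label

    def test_training_set_consistency(self):
        # consistent data (no conflicting duplicate feature vectors) is
        # reproduced exactly by the induced tree
        rng = np.random.default_rng(5)
        words = ["apple", "berry", "cedar", "dune"]
        for _ in range(20):
            seen = {}
            examples = []
            for _ in range(12):
                present = tuple(bool(rng.integers(2)) for _ in words)
                label = seen.setdefault(present, int(rng.integers(3)))
                text = " ".join(w for w, p in zip(words, present) if p)
                examples.append(LabeledExample(text, label))
            tree = train_id3(examples, vocabulary=words)
            for e in examples:
                assert classify(tree, e.text) == e.label

    def test_determinism(self):
        cfg = synth.CorpusConfig(n_trials=40, seed=9)
        ex = synth.generate_training_set(cfg, "pain")
        assert train_id3(ex) == train_id3(list(ex))

    def test_no_word_repeats_on_any_path(self):
        cfg = synth.CorpusConfig(n_trials=60, seed=2)
        tree = train_id3(synth.generate_training_set(cfg, "invasiveness"))

        def check(node, path):
            if isinstance(node, Leaf):
                return
            assert node.word not in path
            check(node.present, path | {node.word})
            check(node.absent, path | {node.word})

        check(tree, set())


class TestClassify:
    def test_leaf_returns_label(self):
        assert classify(Leaf(MEDIUM), "anything at all") == MEDIUM

    def test_one_step_walk(self):
        tree = Node("biopsy", Leaf(HIGH), Leaf(LOW))
        assert classify(tree, "a biopsy tomorrow") == HIGH
        assert classify(tree, "no procedures") == LOW

    def test_serialization_round_trip(self):
        tree = Node("biopsy", Leaf(HIGH), Node("survey", Leaf(LOW), Leaf(MEDIUM)))
        assert tree_from_dict(tree_to_dict(tree)) == tree


class TestInferCriteria:
    def test_constant_models(self, small_corpus):
        records, _ = small_corpus
        models = {"pain": Leaf(LOW), "invasiveness": Leaf(MEDIUM),
                  "time_burden": Leaf(HIGH)}
        ic = infer_criteria(records[0], models)
        assert (ic.pain, ic.invasiveness, ic.time_burden) == (0, 1, 2)

    def test_planted_marker_in_procedures_text(self, small_corpus):
        records, gold = small_corpus
        models = {c: Leaf(LOW) for c in CRITERIA}
        models["pain"] = Node("painful", Leaf(HIGH), Leaf(LOW))
        for r in records:
            if "painful" in r.procedures_text:
                assert infer_criteria(r, models).pain == HIGH
                break
        else:
            pytest.fail("no high-pain trial in fixture corpus")

    def test_missing_model_rejected(self, small_corpus):
        records, _ = small_corpus
        with pytest.raises(ValueError, match="missing models"):
            infer_criteria(records[0], {"pain": Leaf(LOW)})


class TestSklearnEstimator:
    def test_fit_predict_and_clone(self):
        cfg_tr = synth.CorpusConfig(n_trials=50, seed=21)
        cfg_te = synth.CorpusConfig(n_trials=30, seed=22)
        train = synth.generate_training_set(cfg_tr, "time_burden")
        test = synth.generate_training_set(cfg_te, "time_burden")
        clf = Id3Classifier()
        assert clone(clf).get_params() == clf.get_params()
        clf.fit([e.text for e in train], [e.label for e in train])
        assert hasattr(clf, "tree_") and len(clf.vocabulary_) > 0
        acc = (clf.predict([e.text for e in test])
               == np.array([e.label for e in test])).mean()
        assert acc == 1.0

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            Id3Classifier().predict(["text"])
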