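"""ID3 decision trees over boolean word-occurrence features.

Each of the three subjective trial attributes used for ranking -- pain,
invasiveness, and time burden -- is predicted by its own decision tree,
induced with the classic ID3 algorithm: at every node, split on the
unused vocabulary word of maximal information gain (entropy reduction)
over the present/absent partition, stopping at pure nodes, exhausted
vocabulary, or when no word yields positive gain.  Features are plain
word-occurrence booleans: a word is present iff it appears as a whole
lowercase alphabetic token in the text.

Labels are ordinal: LOW=0, MEDIUM=1, HIGH=2.

The module exposes both a functional API (``train_id3`` / ``classify``)
and a scikit-learn-style estimator (:class:`Id3Classifier`) so the model
can sit in sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import TrialRecord

__all__ = [
    "LOW",
    "MEDIUM",
    "HIGH",
    "LEVEL_NAMES",
    "CRITERIA",
    "LabeledExample",
    "Leaf",
    "Node",
    "InferredCriteria",
    "tokenize",
    "featurize",
    "entropy",
    "information_gain",
    "train_id3",
    "classify",
    "infer_criteria",
    "tree_to_dict",
    "tree_from_dict",
    "default_stopwords",
    "Id3Classifier",
]

LOW, MEDIUM, HIGH = 0, 1, 2
LEVELS = (LOW, MEDIUM, HIGH)
LEVEL_NAMES = {"low": LOW, "medium": MEDIUM, "high": HIGH}
LEVEL_LABELS = {LOW: "low", MEDIUM: "medium", HIGH: "high"}

#: The three inferred ranking criteria, in canonical order.
CRITERIA = ("pain", "invasiveness", "time_burden")

_TOKEN_RE = re.compile(r"[a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase maximal alphabetic runs; every other character separates."""
    return _TOKEN_RE.findall(text.lower())


def featurize(text: str, vocabulary: Iterable[str]) -> dict[str, bool]:
    """Boolean word-occurrence vector over ``vocabulary``.

    A word maps to True iff it occurs as a whole token of ``text`` under
    :func:`tokenize` (so "pre-biopsy" contains the token "biopsy").
    """
    vocab = list(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be nonempty")
    present = set(tokenize(text))
    return {w: w in present for w in vocab}


@dataclass(frozen=True)
class LabeledExample:
    """A hand-rated (or synthetically generated) training example."""

    text: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in LEVELS:
            raise ValueError(f"label must be in {LEVELS}, got {self.label!r}")


@dataclass(frozen=True)
class Leaf:
    label: int


@dataclass(frozen=True)
class Node:
    word: str
    present: "Leaf | Node"
    absent: "Leaf | Node"


Tree = Leaf | Node


@dataclass(frozen=True)
class InferredCriteria:
    """The three ordinal subjective labels assigned to one trial."""

    pain: int
    invasiveness: int
    time_burden: int

    def __post_init__(self) -> None:
        for name in CRITERIA:
            if getattr(self, name) not in LEVELS:
                raise ValueError(f"{name} must be in {LEVELS}")

    def level(self, criterion: str) -> int:
        return getattr(self, criterion)


def entropy(label_counts: Sequence[int] | Mapping[object, int]) -> float:
    """Shannon entropy in bits of a label-count distribution."""
    counts = (
        list(label_counts.values())
        if isinstance(label_counts, Mapping)
        else list(label_counts)
    )
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("entropy undefined for zero total count")
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def information_gain(
    examples: Sequence[tuple[Mapping[str, bool], int]], word: str
) -> float:
    """Entropy reduction from partitioning ``examples`` on ``word``.

    ``examples`` are (feature-vector, label) pairs; an empty branch
    contributes zero to the weighted child entropy.
    """
    if not examples:
        raise ValueError("examples must be nonempty")
    labels = [lab for _, lab in examples]
    parent = entropy(Counter(labels))
    present = [lab for fv, lab in examples if fv[word]]
    absent = [lab for fv, lab in examples if not fv[word]]
    n = len(examples)
    child = 0.0
    for branch in (present, absent):
        if branch:
            child += len(branch) / n * entropy(Counter(branch))
    return parent - child


def default_stopwords() -> frozenset[str]:
    """The shipped stopword list (common English function words)."""
    text = (
        resources.files("trialtalk.data").joinpath("stopwords.txt").read_text()
    )
    return frozenset(w for w in text.split() if w)


def _majority(labels: Sequence[int]) -> int:
    # ties resolved toward the lowest ordinal label, for determinism
    counts = Counter(labels)
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def _grow(
    examples: list[tuple[dict[str, bool], int]],
    words: list[str],
) -> Tree:
    labels = [lab for _, lab in examples]
    if len(set(labels)) == 1:
        return Leaf(labels[0])
    if not words:
        return Leaf(_majority(labels))
    gains = [(information_gain(examples, w), w) for w in words]
    # maximal gain; ties toward the lexicographically smallest word
    best_gain = max(g for g, _ in gains)
    if best_gain <= 1e-12:
        return Leaf(_majority(labels))
    best_word = min(w for g, w in gains if g >= best_gain - 1e-12)
    remaining = [w for w in words if w != best_word]
    present = [(fv, lab) for fv, lab in examples if fv[best_word]]
    absent = [(fv, lab) for fv, lab in examples if not fv[best_word]]
    if not present or not absent:
        # cannot happen when gain > 0, kept as a guard
        return Leaf(_majority(labels))
    return Node(
        word=best_word,
        present=_grow(present, remaining),
        absent=_grow(absent, remaining),
    )


def train_id3(
    examples: Sequence[LabeledExample],
    vocabulary: Iterable[str] | None = None,
    stopwords: Iterable[str] | None = None,
) -> Tree:
    """Greedy ID3 induction from labeled texts.

    When ``vocabulary`` is None it is derived from the training texts:
    every token minus the stopword list (the shipped list by default).
    An empty vocabulary yields a single majority leaf.
    """
    if not examples:
        raise ValueError("examples must be nonempty")
    if vocabulary is None:
        stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
        vocab = sorted(
            {t for ex in examples for t in tokenize(ex.text)} - stop
        )
    else:
        vocab = sorted(set(vocabulary))
    labels = [ex.label for ex in examples]
    if not vocab:
        return Leaf(_majority(labels))
    featurized = [(featurize(ex.text, vocab), ex.label) for ex in examples]
    return _grow(featurized, vocab)


def classify(tree: Tree, text: str) -> int:
    """Walk the tree on the token set of ``text``; return the leaf label."""
    present = set(tokenize(text))
    node = tree
    while isinstance(node, Node):
        node = node.present if node.word in present else node.absent
    return node.label


def infer_criteria(
    record: TrialRecord, models: Mapping[str, Tree]
) -> InferredCriteria:
    """Apply the three criterion trees to a trial's combined free text."""
    missing = [c for c in CRITERIA if c not in models]
    if missing:
        raise ValueError(f"missing models for criteria: {missing}")
    text = record.combined_text()
    return InferredCriteria(
        **{c: classify(models[c], text) for c in CRITERIA}
    )


def tree_to_dict(tree: Tree) -> dict:
    if isinstance(tree, Leaf):
        return {"leaf": tree.label}
    return {
        "word": tree.word,
        "present": tree_to_dict(tree.present),
        "absent": tree_to_dict(tree.absent),
    }


def tree_from_dict(d: Mapping) -> Tree:
    if "leaf" in d:
        return Leaf(int(d["leaf"]))
    return Node(
        word=d["word"],
        present=tree_from_dict(d["present"]),
        absent=tree_from_dict(d["absent"]),
    )


def save_tree(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=2)


def load_tree(path) -> Tree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


class Id3Classifier(ClassifierMixin, BaseEstimator):
    """scikit-learn-style wrapper around the ID3 word-occurrence tree.

    Parameters
    ----------
    vocabulary : iterable of str, optional
        Feature words.  When None the vocabulary is the training tokens
        minus ``stopwords``.
    stopwords : iterable of str, optional
        Words excluded from an auto-derived vocabulary; defaults to the
        shipped list.

    Attributes
    ----------
    tree_ : Leaf | Node
        The induced decision tree.
    vocabulary_ : tuple of str
        The feature words actually used.
    classes_ : ndarray
        Sorted unique training labels.
    """

    def __init__(self, vocabulary=None, stopwords=None):
        self.vocabulary = vocabulary
        self.stopwords = stopwords

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "Id3Classifier":
        X = list(X)
        y = [int(v) for v in y]
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        examples = [LabeledExample(text, lab) for text, lab in zip(X, y)]
        self.tree_ = train_id3(
            examples, vocabulary=self.vocabulary, stopwords=self.stopwords
        )
        if self.vocabulary is not None:
            self.vocabulary_ = tuple(sorted(set(self.vocabulary)))
        else:
            stop = (
                frozenset(self.stopwords)
                if self.stopwords is not None
                else default_stopwords()
            )
            self.vocabulary_ = tuple(
                sorted({t for ex in examples for t in tokenize(ex.text)} - stop)
            )
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "tree_"):
            raise ValueError("Id3Classifier is not fitted yet")
        return np.array([classify(self.tree_, text) for text in X])
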