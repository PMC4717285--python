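"""Seeded synthetic data: trial corpora, training sets, RCT outcome tables.

The original trial database and its hand-rated training labels are not
public, so every other module is exercised on generated stand-ins:

* :func:`generate_corpus` builds trial records whose indexed facets are
  drawn from configurable categoricals and whose free text is assembled
  from sentence templates with one marker-word slot per subjective
  criterion (pain, invasiveness, time burden).  Each trial samples a
  gold level per criterion; with probability ``association_strength``
  a marker from that level's pool is embedded (otherwise a neutral
  filler), and with probability ``label_noise`` the emitted gold label
  is flipped to a random other level.  Marker words within a level are
  assigned round-robin from a seed-shuffled pool so that every pool
  word is exercised once a level has at least as many trials as the
  pool has words.
* :func:`generate_training_set` yields (text, label) pairs by the same
  mechanism, for training the ID3 classifiers.
* :func:`generate_rct_outcomes` simulates a two-arm randomized study:
  per-participant Bernoulli outcomes (completion, declared find,
  correct find) and discrete 1-7 rating measures per arm.

All generators are pure functions of their config (seed included): the
same config always produces the same output, with a single random stream
consumed in documented field order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .id3 import CRITERIA, LEVELS, InferredCriteria, LabeledExample
from .records import Phase, SexEligibility, TrialRecord, TrialType

__all__ = [
    "DEFAULT_MARKER_POOLS",
    "CorpusConfig",
    "RctConfig",
    "generate_corpus",
    "generate_training_set",
    "generate_rct_outcomes",
    "discretized_rating_distribution",
]

#: Marker-word pools per criterion and level (LOW=0, MEDIUM=1, HIGH=2).
#: Plausible clinical vocabulary; purely illustrative and configurable.
#: Pools are disjoint across levels of the same criterion.
DEFAULT_MARKER_POOLS: dict[str, dict[int, tuple[str, ...]]] = {
    "pain": {
        0: ("questionnaires", "counseling", "discussions"),
        1: ("injections", "venipuncture", "swabs"),
        2: ("biopsies", "debridement", "thoracentesis"),
    },
    "invasiveness": {
        0: ("registry", "observation", "telephone"),
        1: ("endoscopy", "catheterization", "aspiration"),
        2: ("surgery", "transplantation", "resection"),
    },
    "time_burden": {
        0: ("brief", "short", "single"),
        1: ("monthly", "periodic", "intermittent"),
        2: ("daily", "overnight", "prolonged"),
    },
}

#: Uninformative fillers used when a marker is not embedded; drawn
#: independently of the labels so they carry no signal.
_NEUTRAL_FILLERS = ("routine", "standard", "usual")

#: Per-criterion sentence fragments, one per level.  Each fragment carries
#: level-specific phrasing (texts describing the same burden share wording)
#: and a ``{w}`` slot for the rotating marker word.  When a marker is not
#: embedded (association_strength < 1) the neutral fragment is used instead.
_CRITERION_SENTENCES: dict[str, dict[int, str]] = {
    "pain": {
        0: "Most visits are gentle, involving {w} and conversation only.",
        1: "Some parts of the study can be uncomfortable, such as {w}.",
        2: "A few procedures are painful, for example {w}.",
    },
    "invasiveness": {
        0: "The study is observational, drawing on {w} records.",
        1: "The study involves procedural care, including {w}.",
        2: "The study centers on operative treatment, namely {w}.",
    },
    "time_burden": {
        0: "The time commitment is light, with a {w} clinic visit.",
        1: "The time commitment is moderate, with {w} clinic visits.",
        2: "The time commitment is demanding, with {w} clinic visits.",
    },
}

_NEUTRAL_SENTENCES: dict[str, str] = {
    "pain": "Visits follow the clinic's usual pattern of {w} checks.",
    "invasiveness": "Care follows {w} practice at each participating site.",
    "time_burden": "Clinic visits keep to the {w} outpatient schedule.",
}

_DEFAULT_CANCER_TYPES = {
    "Breast Cancer": 0.25,
    "Lung Cancer": 0.20,
    "Prostate Cancer": 0.20,
    "Colon Cancer": 0.20,
    "Leukemia": 0.15,
}

_DEFAULT_PHASES = {
    Phase.I: 0.2,
    Phase.II: 0.3,
    Phase.III: 0.25,
    Phase.IV: 0.1,
    Phase.UNSPECIFIED: 0.15,
}

_DEFAULT_TRIAL_TYPES = {
    TrialType.TREATMENT: 0.45,
    TrialType.PREVENTION: 0.12,
    TrialType.DIAGNOSTIC: 0.12,
    TrialType.SCREENING: 0.11,
    TrialType.SUPPORTIVE: 0.10,
    TrialType.SURVEY: 0.10,
}

_DEFAULT_SEXES = {
    SexEligibility.ANY: 0.8,
    SexEligibility.FEMALE: 0.1,
    SexEligibility.MALE: 0.1,
}

_DEFAULT_REGIONS = ("NORTHEAST", "SOUTHEAST", "MIDWEST", "SOUTHWEST", "WEST")


def _normalize(weights: Mapping) -> tuple[list, np.ndarray]:
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("categorical weights must be nonnegative and sum > 0")
    return keys, w / w.sum()


@dataclass(frozen=True)
class CorpusConfig:
    """Configuration for synthetic trial corpora and training sets."""

    n_trials: int = 200
    seed: int = 0
    cancer_types: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CANCER_TYPES)
    )
    phases: Mapping[Phase, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHASES)
    )
    trial_types: Mapping[TrialType, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRIAL_TYPES)
    )
    sexes: Mapping[SexEligibility, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEXES)
    )
    regions: tuple[str, ...] = _DEFAULT_REGIONS
    p_any_location: float = 0.3
    p_investigational_drug: float = 0.4
    marker_pools: Mapping[str, Mapping[int, Sequence[str]]] = field(
        default_factory=lambda: DEFAULT_MARKER_POOLS
    )
    association_strength: float = 1.0
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        for name in ("association_strength", "label_noise", "p_any_location",
                     "p_investigational_drug"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for criterion in CRITERIA:
            pools = self.marker_pools.get(criterion)
            if pools is None or set(pools) != set(LEVELS):
                raise ValueError(
                    f"marker_pools[{criterion!r}] must define all levels {LEVELS}"
                )
            seen: set[str] = set()
            for level in LEVELS:
                words = set(pools[level])
                if not words:
                    raise ValueError(f"empty marker pool: {criterion}/{level}")
                if words & seen:
                    raise ValueError(
                        f"marker pools overlap across levels of {criterion}: "
                        f"{sorted(words & seen)}"
                    )
                seen |= words


class _RoundRobin:
    """Cycle a seed-shuffled pool so every word is exercised evenly."""

    def __init__(self, pool: Sequence[str], rng: np.random.Generator):
        order = list(pool)
        rng.shuffle(order)
        self._cycle = itertools.cycle(order)

    def next(self) -> str:
        return next(self._cycle)


_PURPOSE_TEMPLATE = (
    "The purpose of this study is to learn whether a new approach can help "
    "people with {cancer}. {inv}"
)
_PROCEDURES_TEMPLATE = (
    "Visits take place at the study clinic, with support from the study "
    "team during follow-up. {pain}"
)
_ELIGIBILITY_TEMPLATE = (
    "Adults aged {lo} to {hi} may be able to join. {time}"
)


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[TrialRecord], dict[str, InferredCriteria]]:
    """Generate trial records plus the gold subjective labels per trial.

    Returns ``(records, gold)`` where ``gold[trial_id]`` holds the
    emitted (possibly noise-flipped) level per criterion.  Gold level
    triples are pre-assigned in balanced shuffled blocks of the 27 level
    combinations, so the three criteria are mutually uninformative by
    construction.  The random stream is consumed in documented order:
    marker-pool shuffles, level-block shuffles, then per trial: cancer
    type, phase, trial type, sex, locations, ages, drug flag, title
    token, then per criterion (canonical order): embedding coin, noise
    coin (+ flip choice when it fires).
    """
    rng = np.random.default_rng(config.seed)
    cancers, p_cancer = _normalize(config.cancer_types)
    phases, p_phase = _normalize(config.phases)
    ttypes, p_ttype = _normalize(config.trial_types)
    sexes, p_sex = _normalize(config.sexes)
    robins = {
        (c, lvl): _RoundRobin(config.marker_pools[c][lvl], rng)
        for c in CRITERIA
        for lvl in LEVELS
    }
    neutral = _RoundRobin(_NEUTRAL_FILLERS, rng)
    combos = list(itertools.product(LEVELS, LEVELS, LEVELS))
    triples: list[tuple[int, int, int]] = []
    while len(triples) < config.n_trials:
        block = list(combos)
        rng.shuffle(block)
        triples.extend(block)

    records: list[TrialRecord] = []
    gold: dict[str, InferredCriteria] = {}
    for i in range(config.n_trials):
        cancer = cancers[rng.choice(len(cancers), p=p_cancer)]
        phase = phases[rng.choice(len(phases), p=p_phase)]
        ttype = ttypes[rng.choice(len(ttypes), p=p_ttype)]
        sex = sexes[rng.choice(len(sexes), p=p_sex)]
        if rng.random() < config.p_any_location:
            locations: frozenset[str] = frozenset()
        else:
            k = int(rng.integers(1, min(3, len(config.regions)) + 1))
            idx = rng.choice(len(config.regions), size=k, replace=False)
            locations = frozenset(config.regions[j] for j in sorted(idx))
        min_age = int(rng.integers(18, 61))
        max_age = min(min_age + int(rng.integers(10, 41)), 99)
        uses_drug = bool(rng.random() < config.p_investigational_drug)
        compound = f"XB-{int(rng.integers(100, 1000))}"

        levels: dict[str, int] = {}
        sentences: dict[str, str] = {}
        for criterion, level in zip(CRITERIA, triples[i]):
            if rng.random() < config.association_strength:
                word = robins[(criterion, level)].next()
                sentence = _CRITERION_SENTENCES[criterion][level].format(w=word)
            else:
                sentence = _NEUTRAL_SENTENCES[criterion].format(w=neutral.next())
            sentences[criterion] = sentence
            emitted = level
            if config.label_noise > 0 and rng.random() < config.label_noise:
                others = [l for l in LEVELS if l != level]
                emitted = others[int(rng.integers(0, 2))]
            levels[criterion] = emitted

        trial_id = f"NCT{i:07d}"
        record = TrialRecord(
            trial_id=trial_id,
            full_title=(
                f"A Randomized Study of {compound} in Subjects With {cancer}"
            ),
            phase=phase,
            trial_type=ttype,
            cancer_type=cancer,
            min_age=min_age,
            max_age=max_age,
            sex_eligibility=sex,
            locations=locations,
            uses_investigational_drug=uses_drug,
            purpose_text=_PURPOSE_TEMPLATE.format(
                cancer=cancer, inv=sentences["invasiveness"]
            ),
            procedures_text=_PROCEDURES_TEMPLATE.format(pain=sentences["pain"]),
            eligibility_text=_ELIGIBILITY_TEMPLATE.format(
                lo=min_age, hi=max_age, time=sentences["time_burden"]
            ),
        )
        records.append(record)
        gold[trial_id] = InferredCriteria(**levels)
    return records, gold


def generate_training_set(
    config: CorpusConfig, criterion: str
) -> list[LabeledExample]:
    """Labeled (text, level) pairs for one criterion, same mechanism as
    :func:`generate_corpus` (the text is the trial's combined free text)."""
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    records, gold = generate_corpus(config)
    return [
        LabeledExample(text=r.combined_text(), label=gold[r.trial_id].level(criterion))
        for r in records
    ]


def discretized_rating_distribution(
    mean: float, sd: float, points: Sequence[int] = tuple(range(1, 8))
) -> dict[int, float]:
    """Discrete distribution on the 1-7 scale: normal density at each
    point, renormalized.  Convenience for configuring rating measures."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    pts = np.asarray(points, dtype=float)
    w = np.exp(-0.5 * ((pts - mean) / sd) ** 2)
    w = w / w.sum()
    return {int(p): float(v) for p, v in zip(points, w)}


def _default_rating_measures() -> dict[str, dict[str, dict[int, float]]]:
    return {
        "satisfaction": {
            "agent": discretized_rating_distribution(4.8, 1.9),
            "control": discretized_rating_distribution(3.2, 1.7),
        },
        "criteria_match": {
            "agent": discretized_rating_distribution(4.8, 1.7),
            "control": discretized_rating_distribution(3.4, 1.9),
        },
    }


@dataclass(frozen=True)
class RctConfig:
    """Two-arm randomized-study simulation parameters.

    Defaults emulate the standardized-search-task conditions: 43 vs 46
    participants, completion ~84%/80%, declared-find ~48%/40%,
    correct-find ~43%/31%, and 1-7 rating measures centered where the
    two arms' satisfaction and criteria-match ratings sit.
    """

    arms: tuple[str, str] = ("agent", "control")
    n_per_arm: tuple[int, int] = (43, 46)
    p_completed: tuple[float, float] = (0.84, 0.80)
    p_declared: tuple[float, float] = (0.48, 0.40)
    p_correct: tuple[float, float] = (0.43, 0.31)
    rating_measures: Mapping[str, Mapping[str, Mapping[int, float]]] = field(
        default_factory=_default_rating_measures
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_arm):
            raise ValueError("n_per_arm must be nonnegative")
        for name in ("p_completed", "p_declared", "p_correct"):
            for p in getattr(self, name):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name} entries must lie in [0, 1]")
        for measure, per_arm in self.rating_measures.items():
            for arm in self.arms:
                if arm not in per_arm:
                    raise ValueError(f"rating {measure!r} missing arm {arm!r}")


def generate_rct_outcomes(config: RctConfig) -> pd.DataFrame:
    """Simulate one participant per row: arm, three 0/1 outcomes, and one
    ``rating_<measure>`` column per configured measure.

    Draws are independent per participant, consumed in the order:
    completed, declared_found, found_correct, then each rating measure
    in configuration order.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for arm_idx, arm in enumerate(config.arms):
        dists = {}
        for measure, per_arm in config.rating_measures.items():
            keys, probs = _normalize(per_arm[arm])
            dists[measure] = (keys, probs)
        for _ in range(config.n_per_arm[arm_idx]):
            row = {
                "arm": arm,
                "completed": int(rng.random() < config.p_completed[arm_idx]),
                "declared_found": int(rng.random() < config.p_declared[arm_idx]),
                "found_correct": int(rng.random() < config.p_correct[arm_idx]),
            }
            for measure, (keys, probs) in dists.items():
                row[f"rating_{measure}"] = int(
                    keys[rng.choice(len(keys), p=probs)]
                )
            rows.append(row)
    columns = ["arm", "completed", "declared_found", "found_correct"] + [
        f"rating_{m}" for m in config.rating_measures
    ]
    return pd.DataFrame(rows, columns=columns)
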