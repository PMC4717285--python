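# trialtalk

Conversational, fully faceted clinical-trial search — a library and CLI
for building search interfaces that people with low health literacy can
actually use.

Conventional keyword search engines are a real barrier for the roughly
one in three adults with low health literacy, and clinical-trial
databases are among the hardest targets: long titles, dense eligibility
prose, and jargon-heavy protocol descriptions. `trialtalk` implements
the text-and-dialog core of a conversational trial search system: a
scripted agent interviews the user with multiple-choice questions (the
user never types free text), searches a trial database on indexed
facets, ranks results by subjective criteria inferred from trial text,
and presents each trial in staged levels of detail with an integrated
plain-language dictionary. It also ships the nonparametric statistics
used to evaluate such an interface against a control in a two-arm
randomized study.

## What is inside

- **Trial store** (`trialtalk.records`) — a validated `TrialRecord`
  model with seven indexed facets (age range, sex, cancer type,
  locations, trial type, phase I–IV, investigational-drug flag) and
  three free-text sections; JSONL corpora; simplified display titles
  ("Phase II Treatment Trial for Lung Cancer"); three staged detail
  views (title + eligibility → + purpose → + procedures).
- **Criteria inference** (`trialtalk.id3`) — ID3 decision trees over
  boolean word-occurrence features that assign each trial three ordinal
  labels used for ranking: pain, invasiveness, and time burden, each in
  {low=0, medium=1, high=2}. At every node the tree splits on the
  unused word *w* maximizing the information gain
  `H(S) − Σ_b (|S_b|/|S|) H(S_b)` over the present/absent partition,
  where `H(S) = −Σ_i p_i log2 p_i`. Also exposed as a scikit-learn
  estimator (`Id3Classifier`).
- **Search engine** (`trialtalk.search`) — eligibility filtering on any
  subset of facets, ranking by the preference mismatch score
  `Σ_c |inferred_c − desired_c|`, and single-facet query relaxations
  with hit counts when a search comes up empty.
- **Dialog engine** (`trialtalk.dialog`) — an augmented-transition-
  network session manager driven by a YAML script: interview →
  criteria confirmation → search → staged presentation (with
  difficult-term dictionary, bookmarking, education subnetworks) →
  refinement → summary of views → farewell. Sessions are deterministic
  and replayable from a recorded choice sequence.
- **Synthetic data** (`trialtalk.synth`) — seeded generators for trial
  corpora with planted word→label associations (configurable
  association strength and label noise), training sets, and simulated
  two-arm study outcome tables.
- **Evaluation statistics** (`trialtalk.stats`) — uncorrected Pearson
  chi-square on 2×2 tables, `χ² = n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`
  with 1 df; the Mann-Whitney U test (`U = min(U₁, n₁n₂−U₁)`, exact
  enumeration for n₁+n₂ ≤ 10, tie-corrected normal approximation
  otherwise); and outcome-table summaries (counts with percentages,
  means with sample SDs).

## Worked example

```python
from trialtalk import (
    CorpusConfig, FacetQuery, Preferences, TrialType, ANYWHERE,
    generate_corpus, generate_training_set, train_id3, infer_criteria,
    filter_trials, rank_trials, simplify_title,
    ContingencyTable2x2, chi_square_2x2,
)
from trialtalk.id3 import CRITERIA

records, _ = generate_corpus(CorpusConfig(n_trials=200, seed=13))
models = {
    c: train_id3(generate_training_set(CorpusConfig(n_trials=54, seed=6), c))
    for c in CRITERIA
}
inferred = {r.trial_id: infer_criteria(r, models) for r in records}

query = FacetQuery(age=70, cancer_type="Breast Cancer",
                   trial_type=TrialType.TREATMENT, location=ANYWHERE)
hits = filter_trials(records, query)
ranked = rank_trials(hits, Preferences(pain=0), inferred)
print(f"{len(hits)} eligible trials")
for r in ranked[:3]:
    ic = inferred[r.trial_id]
    print(r.trial_id, "|", simplify_title(r), "| pain level", ic.pain)

res = chi_square_2x2(ContingencyTable2x2(5, 9, 0, 8))
print(f"chi2 = {res.statistic:.2f}, p = {res.p_value:.3f}")
```

prints

```
9 eligible trials
NCT0000036 | Phase II Treatment Trial for Breast Cancer | pain level 0
NCT0000134 | Phase I Treatment Trial for Breast Cancer | pain level 0
NCT0000162 | Phase III Treatment Trial for Breast Cancer | pain level 0
chi2 = 3.70, p = 0.054
```

Nine of the 200 synthetic trials accept a 70-year-old breast-cancer
patient looking for a treatment trial anywhere; the top-ranked ones are
those whose text the trained models classify as low-pain, matching the
stated preference. The chi-square line tests a 2×2 outcome table in
which 5 of 14 participants in one arm succeeded at a task versus 0 of 8
in the other (statistic 3.70, two-sided p ≈ .05).

The same pipeline is available from the shell:

```bash
trialtalk synth corpus --n 200 --seed 13 -o corpus.jsonl --gold gold.csv
trialtalk train train_pain.csv --criterion pain -o models/pain.json
trialtalk search corpus.jsonl --age 70 --cancer "Breast Cancer" \
    --type treatment --location anywhere --models models --prefer-pain low
trialtalk chat corpus.jsonl --models models          # interactive session
trialtalk evaluate outcomes.csv --report report.md   # two-arm study report
```

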