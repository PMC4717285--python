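# Methods

## The retrieval model

Search is *fully faceted*: the user never types a query. A
`FacetQuery` sets any subset of the seven indexed eligibility facets;
an unset facet matches every trial. The matching predicate is a
conjunction over set facets:

- age: `min_age ≤ age ≤ max_age`, inclusive on both bounds;
- sex: the trial accepts the user's sex when its eligibility is ANY or
  equal;
- cancer type, trial type, phase: equality on the controlled value;
- location: a query of ANYWHERE matches everything; a trial with no
  listed locations is treated as offered anywhere; otherwise the
  queried region code must be among the trial's locations;
- investigational drug: `investigational_drug_ok=False` excludes
  trials that use one; `True` imposes no constraint (tolerance, not a
  requirement).

Matching trials keep corpus order. Ranking then uses the three
text-inferred ordinal attributes: for each criterion with a stated
preference the mismatch is `|inferred − desired|`, and trials are
sorted by the summed mismatch, ascending. Ties break on `trial_id` so
output is deterministic; when no preference is set at all there is no
ranking signal and the corpus order is preserved rather than reordered
by id. When a query yields nothing (or the user exhausts the list),
single-facet relaxations are offered: each set facet is unset alone, in
the fixed priority order phase → trial type → location → drug
tolerance → cancer type → sex → age (least clinically constraining
first; this order is configuration, not data), and a relaxation is
reported only if it recovers at least one trial, together with its hit
count.

## Inferred criteria: ID3 over word occurrence

Pain, invasiveness, and time burden are not database fields; they are
predicted from trial text by three independent decision trees, one per
criterion, on a three-level ordinal scale (low=0, medium=1, high=2).
Features are boolean word occurrences: the text is tokenized into
lowercase maximal alphabetic runs (every other character separates, so
"pre-biopsy" yields the token "biopsy"), and a vocabulary word is
present iff it appears as a whole token. Unless a vocabulary is given,
it is the set of training-set tokens minus a small shipped stopword
list of English function words.

Induction is plain ID3: at each node choose the unused word with
maximal information gain (bits) over the present/absent partition;
recurse; stop at pure nodes, exhausted vocabulary, or when no word has
positive gain (within 1e-12). Leaves carry the majority label of their
examples. There is no pruning and no minimum leaf size. Determinism is
guaranteed by two tie-break rules: equal-gain words resolve to the
lexicographically smallest, and majority ties resolve to the lowest
ordinal label. Classification of a trial applies each tree to the
concatenation of its purpose, procedures, and eligibility text (the
three fields are concatenated rather than classified separately because
the level signal may appear in any of them).

`Id3Classifier` wraps the same algorithm in a scikit-learn estimator
(fit/predict, `tree_` and `vocabulary_` attributes) so the model can
participate in sklearn pipelines and model selection.

## Dialog management

The session is an augmented transition network: states with outgoing
arcs carrying guards, actions, and subnetwork calls, defined in a YAML
script. Interaction is system-initiated at the adjacency-pair level —
each turn the agent speaks (template text with `{slot}` substitution;
rendering fails loudly on a missing slot) and offers an ordered menu;
the only free-text user input in the whole design is the display name,
supplied outside the dialog. Eight built-in state kinds provide what a
static script cannot: interview questions whose menus are derived from
the corpus (e.g. the cancer types actually present), preference
questions, criteria confirmation with one "change X" arc per set value,
search execution, staged trial presentation, dictionary display,
refinement offers, and the summary of viewed/bookmarked trials.
Education subnetworks (what a trial is, voluntariness, risk) are
config-defined sub-scripts entered from the tutorial state; a return
state pops back to the caller.

Design rules enforced by the engine:

- **Staged disclosure.** A trial is first shown at level 1 (simplified
  title + eligibility); level 2 adds the purpose, level 3 the
  procedures, and the level can only step up one at a time, so a level-3
  view is always preceded by levels 1 and 2 for that trial.
- **Presentation safety.** Results are recomputed (filter + rank)
  every time the search state is entered, and every query edit (a
  revision via the confirm state, or an applied relaxation) must pass
  through search before presentation resumes; the engine additionally
  re-verifies eligibility of the displayed trial at presentation time
  and refuses to present a stale result.
- **Bookkeeping.** Bookmarks are always a subset of trials viewed; the
  session summary lists viewed trials in order with bookmark flags.
- **Replayability.** A session is a pure function of script, corpus,
  models, and the choice sequence; transcripts serialize to JSONL and
  replay byte-identically.
- **Session time management.** The shipped flow contains legitimate
  cycles (revise loops, the dictionary, re-reading a trial). So that
  every session — including adversarially random ones — terminates, the
  script carries a `wrap_up_after` setting (default 150 turns) after
  which the agent offers only the path to the summary and farewell.

The shipped script's prompt wording is replacement copy written for
this package; the flow (greeting/tutorial → interview over the seven
facets and three preferences → confirmation → search → staged
presentation with dictionary and bookmarking → refinement → summary →
farewell) is the documented default and fully configurable. Difficult
terms are detected by lexicon membership: a case-insensitive
longest-match scan over tokens against a term → plain-language
definition table, each term reported once in first-occurrence order.
Read-aloud is realized as re-display of the text block with an offer to
repeat; the display contract is kept so a speech layer could attach.

## Synthetic data

No public corpus with hand-rated pain/invasiveness/time-burden labels
exists, so the generators create one with known ground truth:

- **Facets** are sampled from configurable categorical distributions
  (five cancer types, phases I–IV/unspecified, six trial types, sex
  eligibility heavily weighted to ANY, 0–3 region codes with a 30%
  chance of "anywhere", 40% investigational-drug rate, ages 18–60 with
  10–40 year spans).
- **Labels** per trial are a (pain, invasiveness, time-burden) triple;
  triples are assigned in balanced shuffled blocks of all 27
  combinations so the three criteria are mutually uninformative by
  construction.
- **Text** is assembled from sentence templates with realistic
  punctuation, hyphens, and mixed case. For each criterion the level
  determines a sentence fragment whose phrasing reflects the level
  (e.g. "The time commitment is demanding, with daily clinic visits")
  and embeds one marker word rotated round-robin from that level's
  pool ("daily", "overnight", "prolonged", …), so every pool word is
  exercised once a level has at least as many trials as its pool has
  words. Pools are disjoint across levels of a criterion and across
  criteria; with probability `1 − association_strength` the sentence is
  replaced by a neutral one carrying no signal, and with probability
  `label_noise` the emitted label is flipped to a random other level
  while the text keeps the original level's wording.
- **Study outcomes** are simulated per participant: two arms with
  configurable sizes, Bernoulli draws for completion, declared find,
  and correct find, plus discrete 1–7 ratings drawn from per-arm
  distributions (a discretized-normal helper builds them from a mean
  and SD). Defaults emulate a standardized-search-task comparison:
  arms of 43 and 46, completion 84%/80%, declared 48%/40%, correct
  43%/31%, satisfaction centered at 4.8 vs 3.2.

Every generator is a pure function of its config (seed included), with
a single random stream consumed in documented field order.

What the generator does *not* emulate: real protocol prose (its
vocabulary and syntax are far richer than three templated sentences),
correlated facets (real trial phase and type are not independent), or
label ambiguity (real "pain" ratings disagree between raters in ways a
flip-noise model does not capture). Passing recovery tests therefore
shows that the learner and pipeline are correct, not that three-level
subjective labels are this separable in real trial text.

Two measured consequences of the design are worth recording. With full
association strength and no noise, ID3 recovers the planted rule with
100% held-out accuracy (50 train / 50 test); this held in 450/450
seeded replications. With 10% label noise at n=200 (held-out sets
noise-free, since the quantity of interest is recovery of the true
rule), unpruned ID3 overfits mildly and held-out accuracy averages
~0.88. At 50% flip noise the emitted label agrees with the
text-determined level only half the time, so accuracy against noisy
labels is bounded near 0.5 and observed around 0.38 once overfitting
is added — i.e. the association degrades toward, but not to, chance.

## Evaluation statistics

Conventions are fixed to match how two-arm interface studies of this
kind report results:

- **Chi-square** on 2×2 frequency tables is the uncorrected Pearson
  statistic `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with 1 df and a
  two-sided p. No Yates continuity correction: the published task
  outcome statistics (1.8, 0.5, 1.3, 3.7) recompute from their printed
  counts only with the uncorrected formula, which is pinned by a
  regression test. A zero margin raises rather than returning 0/0.
- **Mann-Whitney U** uses midranks, reports `min(U₁, n₁n₂−U₁)`, and
  takes its two-sided p from exact enumeration of all group
  assignments when n₁+n₂ ≤ 10 (valid with ties), otherwise from the
  normal approximation with tie-corrected variance
  `n₁n₂/12 · ((n+1) − Σ(t³−t)/(n(n−1)))` and a 0.5 continuity
  correction. The approximation is only ever used above the exact
  cutoff; measured against enumeration it is within 0.02 of the exact
  two-sided p for tie-free samples with both groups ≥ 5, and worse
  below that (0.03 at 4+4, up to ~0.2 for 2+2), which is exactly why
  small samples get the exact branch.
- **Summaries** report counts with percentages for binary outcomes and
  mean with sample SD (n−1 denominator) for ratings; degenerate cells
  (no observations) are flagged absent rather than given a value.

## Problem sizes

Tests and the acceptance script run on corpora of 20–200 trials,
training sets of 50 (clean recovery) and 200 (noisy recovery, 5 seeds ×
3 criteria), 100 random dialog walks capped at 500 turns, 100
corpus/query pairs and 1000 random tables for oracle equivalence, and
all ~300 tie-free small-sample Mann-Whitney outcomes. These sizes make
every property check exact or tightly concentrated while keeping the
full suite fast.

## Known limitations

- The interview's age menu offers decade values only (menus, never free
  text); finer ages enter through the library API.
- The dialog engine's dynamic state kinds are implemented in code, not
  YAML; a script can reorder and reword the flow but not define new
  kinds without extending the engine.
- Audio (speech synthesis, read-aloud playback) and embodied-agent
  animation are out of scope by design; the display contracts are the
  attachment points.
- The evaluation toolkit intentionally applies no multiple-testing
  adjustment; callers comparing many measures should adjust externally
  if their design calls for it.
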