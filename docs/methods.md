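# Methods

This note documents the models and procedures implemented in `abxminer`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what validation on synthetic corpora can
establish.

## Corpus construction

**Inclusion rule.** A message belongs to the analysis corpus iff at least
one antibiotic keyword (or synonym) *and* at least one inefficiency-field
phrase match the same message. Matching is performed on lowercased,
accent-folded text with token-boundary anchoring: French forum text varies
wildly in case and diacritics ("Antibiotique", "antibiotiqué"), and
substring matching would accept words embedding a keyword. The
inefficiency field contains literal phrases ("inefficace", "sans effet")
plus a negated-efficacy construction: "ne … pas" with an efficacy verb
stem (march-, fonctionn-, agi-, guéri-, soign-, soulag-, fai-/fon-) inside
a gap of at most 5 tokens. The gap limit keeps unrelated negations
("ne … pas" spanning a clause boundary) from counting as inefficiency.

**Exclusion cascade.** Removal rules run in a fixed order — non-target
language, animal-related vocabulary, study-specific exclusion words — and
each removed message is attributed to the *first* rule that fires. The
order is a convention chosen for deterministic attribution; the audit
report satisfies `input = output + Σ removed` exactly on every run.
Language identification is stopword-profile scoring: each configured
language profile counts its stopwords among the message tokens and the
top-scoring profile wins. Messages under 3 tokens, or with tied/zero
scores, are tagged "undetermined" and *kept* — a short message is not
evidence of a foreign language. The shipped exclusion-word list is a
documented placeholder (the study-specific list behind the original corpus
is not public); any list can be substituted via a JSON lexicon file.

**Anonymization.** Authors are replaced by a salted SHA-256 prefix
(`u:<16 hex>`); @-handles and URLs become fixed placeholders. The
operation is idempotent (already-hashed authors are recognized), so
re-running a pipeline over its own output is safe.

## Demographics

**Gender** is an additive evidence score per user: a first name in the
username counts 3 (the strongest signal), a gendered username affix 1, and
each gendered lexical-field or adjective/participle agreement occurrence
in the user's messages 1. The prediction is the argmax of the two scores;
ties (including zero evidence) yield "unknown", which is excluded from
gender-share denominators and always reported with its denominator.
Scores are sums, hence permutation-invariant over posts and monotone as
posts accumulate. Agreement word lists deliberately exclude forms whose
accent-folded spelling collides with common nouns (e.g. masculine
"fatigué" → "fatigue", a physical-domain noun).

**Age** is two-stage. Regular expressions over all of a user's posts
("j'ai N ans"; bare "N ans" guarded against duration readings such as
"pris 3 ans de traitement"; "né(e) en YYYY" converted with the post's
timestamp year) take precedence; candidates outside [10, 100] are
rejected, conflicts resolve by majority then most recent post. Only when
no expression matches does a gradient-boosted regression over stylometric
features (message length statistics, emoticon and exclamation rates, comma
rate, sentiment-lexicon hits, source) predict the age, clipped to
[10, 100]. "Probabilistic" prediction is honored by companion quantile
models (default 10%/90%) exposing an interval. An untrained model raises
rather than returning a silent default.

## Biterm topic model

Short messages starve per-document topic models of co-occurrence signal,
so the corpus-wide set of biterms (all unordered token pairs within one
message — the whole post is the co-occurrence window) is modeled as one
mixture: θ ~ Dir(α) over K topics, φ_k ~ Dir(β) over V tokens, each biterm
drawing a topic from θ and both words from that topic's φ.

Preprocessing lowercases, accent-folds, splits on non-letters, drops
stopwords and tokens under 3 characters, and orders the vocabulary by
first occurrence (deterministic ids). Documents left with fewer than two
tokens contribute no biterms but are still assignable through the
single-token mixture.

**Sampler.** Collapsed Gibbs over biterm assignments with the conditional

    P(z_b = k | z₋b) ∝ (n₋b,k + α) · (n₋b,w1|k + β)(n₋b,w2|k + β + [w1=w2])
                       / ((2n₋b,k + Vβ)(2n₋b,k + 1 + Vβ))

The `[w1 = w2]` increment is the exact collapsed conditional when a biterm
repeats a token (the two draws from φ_k are not exchangeable with the
counts held fixed); for distinct tokens it reduces to the standard BTM
form. With this correction the sampler's stationary distribution matches
brute-force posterior enumeration on small corpora *including* self-pair
biterms, which the test suite checks via pairwise co-assignment
probabilities (per-biterm marginals are uniform for any corpus by
topic-label symmetry and would be a vacuous check). The inner sweep is a
numba kernel; all uniform variates are drawn outside by a seeded numpy
Generator, so runs are exactly reproducible and the same kernel serves
batch fitting and stepwise diagnostics.

**Defaults.** α = 50/K, β = 0.01 (common BTM practice), 1000 sweeps with
500 burn-in and thinning 10; φ and θ are averaged over post-burn-in
samples (runs too short for the thinning schedule fall back to the final
state). Averaging across samples assumes the chain does not switch topic
labels mid-run; on separated topics it does not, but for near-degenerate
fits the final-state estimator `phi_from_counts()` is available. K is a
config parameter (default 13, the theme count the pipeline's reporting
emulates); a UMass-coherence sweep utility assists choosing K, since no
selection rule is prescribed.

**Characteristic tokens.** weight(t, k) = φ_t|k / Σ_{k'≠k} φ_t|k' — "the
inverse of the probabilities of this token in other topics" is read as the
inverse of the *sum* over other topics (alternatives: product, max). Top
15 per topic, ties broken by raw φ then token id; K = 1 falls back to raw
φ ranking. Document assignment is argmax of P(k|d) = Σ_b P(k|b)/|d_b| with
P(k|b) ∝ θ_k φ_w1|k φ_w2|k, ties to the lowest topic index, empty
documents → an explicit unassigned sentinel that reporting excludes from
denominators.

## Quality-of-life impact classification

Two stages: a binary *gate* ("does this message express any HRQoL
impact?") then five one-vs-rest category models (physical, psychic,
activity-related, relational, financial) evaluated only when the gate
fires — so no gate-negative message can ever carry a category, and a
single message may carry several. All six are gradient-boosted tree
classifiers (depth 4, 200 rounds, fixed seeds) over one shared feature
vector: sentiment-lexicon hits, first-person pronoun count, lexical
tense/conjugation markers (past, present, conditional), negation count,
per-domain lexical-field hits, and message length — all additive counts.
Category models train only on impact-positive examples; a single-class
target raises an error naming the offending model. The decision threshold
is 0.5, configurable.

The original annotated training corpus behind the published classifier is
unavailable; the *architecture* is the reproduced object and the bundle is
trained on synthetic annotated posts. Reported QoL tables always carry
both published percentage conventions — share of impact-bearing messages
and share of all category mentions — each with its denominator, because
aggregate tables in this literature mix the two.

## Reporting conventions

Half-up rounding everywhere (`decimal`-based, so 0.5 never rounds down):
2 decimals for source/topic-style shares, integer percent for QoL shares.
Every emitted percentage recomputes from its own printed count and
denominator; a self-consistency audit runs in the tests. Partition tables
sum to their denominator; the theme table reproduced from published
counts uses that table's own published denominator (3770), which its rows
do not sum to — the package reports the discrepancy rather than resolving
it, and `topic_table` computed from actual assignments always uses the
true assigned-message count. The seasonality index is the ratio of mean
monthly volume in November–March to April–October over a dense (gap-free)
calendar. The user denominator for gender shares is the number of
gender-determined users and is always printed (published aggregates use
two slightly different user denominators, 2335 and 2337).

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes and
emits full latent ground truth (gender, age, topic, impact set, intended
filter fate with a closed set of reason codes) as the oracle for every
test. Defaults encode the published marginals: 2335 users, shifted-Poisson
posts per user (1 + Poisson(0.62); only the mean is published), female
rate 0.8622, ages from a rounded normal (mean 35, sd 10 — only the mean is
published) clipped to [10, 100], January 2014 – July 2020 calendar with
November–March months upweighted by amplitude 2.0 (seasonality is
published without a ratio), 13 topics with weights proportional to the
published theme counts, source labels drawn with the published source
distribution, impact prevalence 0.63 with conditional category shares
{0.7827, 0.6506, 0.3125, 0.2525, 0.0117}.

Because independent per-category Bernoulli draws conditioned on "at least
one category" inflate marginals, the base probabilities are solved by
fixed point so the *conditional* marginals equal the configured shares
exactly. Topic content is a controlled pseudo-lexicon (3-syllable words,
deterministically generated and checked disjoint from every lexicon and
stopword list) over planted topic distributions: disjoint token blocks of
⌊V/K⌋ tokens holding 95% of each topic's mass, Dirichlet-weighted within
the block. Demographic and impact signal is injected as real French marker
phrases: gendered usernames (probability 0.8 per user), agreement phrases
(0.5 per post), explicit age expressions (0.5 per user), one domain-noun
phrase per true impact category, and age-correlated style (emoticon,
exclamation and comma rates, message length) that carries the learnable
signal for the age-model fallback. Distractor posts are constructed to
trip exactly one exclusion rule each, with the intended reason recorded.

**What passing these tests shows — and does not.** The synthetic "French"
is a marker-phrase scaffold, not language: filter precision/recall of 1.0
establishes that the rules implement their specification exactly, not that
the lexicons are complete for real forums; gender accuracy ≈ 1 and
category recall ≥ 0.85 establish that the scoring and gating architecture
recover a signal that is genuinely present, not that real posts carry such
clean markers. Topic recovery (≥ 90% token overlap, ≥ 85% assignment
accuracy on planted topics) is the standard planted-structure benchmark
for samplers; real themes overlap far more than planted blocks. Results on
real corpora depend on lexicon curation that this package deliberately
keeps configurable.

## Problem sizes and numerical choices

The acceptance script runs the full pipeline at the default study scale
(2335 users ≈ 3.8k posts), fits K = 13 with 400 sweeps / 200 burn-in
(estimates stabilize well before that on corpora this size), trains the
learned stages on an independent 2000-user synthetic corpus, and runs the
planted-topic benchmark at K = 3, V = 300, 2000 documents; generator
marginals are checked at 10⁴ users against exact binomial / CLT intervals.
All randomness descends from the single `--seed` via numpy SeedSequence.
Degenerate inputs are handled explicitly: K > B warns and runs; an empty
topic's φ column is the uniform 1/V smoothing limit; empty documents are
sentinel-unassigned; zero denominators report 0%; β → ∞ drives φ uniform
(tested).

## Known limitations

- Lexicons are compact curated defaults; replicating any particular
  study's filtering requires substituting its exclusion-word list.
- Gender inference is binary by construction of the score comparison;
  users without binary-gendered evidence are "unknown".
- The language profiler distinguishes configured profiles only (default
  French/English) and is intentionally conservative for short texts.
- Tense/conjugation features are lexical approximations, not parses.
- Posterior averaging of φ assumes no label switching within a chain.
- The generator does not model topic correlation, code-switching, irony,
  or spelling noise beyond case/diacritics; classifier scores on it are
  upper bounds relative to real data.
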