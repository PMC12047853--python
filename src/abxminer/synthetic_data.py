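"""Synthetic forum-post generator with full latent ground truth.

Emulates the statistical structure the downstream analysis assumes: a
mostly-female user base around age 35, ~1.6 posts per user, November–March
seasonality of message volume, a biterm-generative topic structure, and
multi-label quality-of-life impact annotations.  The "French" of the corpus
is a controlled pseudo-lexicon for topic content plus a small set of real
French marker phrases (inclusion clauses, gendered agreements, age
expressions, HRQoL domain nouns) so that every rule-based stage is
exercised without a language model.

Every generated post carries latent labels (gender, age, topic, impact set,
intended filter fate) in a parallel ground-truth table, the oracle for all
recovery tests.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .lexicons import LexiconSet, default_lexicons, QOL_CATEGORIES
from .corpus_filter import (REASON_KEPT, REASON_NO_INCLUSION, REASON_LANGUAGE,
                            REASON_ANIMAL, REASON_EXCLUSION)

WINTER_MONTHS = (11, 12, 1, 2, 3)  # the November–March high season

#: conditional-on-impact category shares matching the published QoL table
DEFAULT_CATEGORY_SHARES = {
    c: reference.QOL_COUNTS[c] / reference.N_IMPACT_POSTS
    for c in QOL_CATEGORIES
}


class ConfigurationError(ValueError):
    """Raised when a GenerationConfig cannot produce a valid corpus."""


@dataclass
class GenerationConfig:
    """Knobs of the generator; defaults reproduce the study-scale marginals."""

    n_users: int = reference.N_USERS
    posts_per_user_mean: float = reference.MEAN_POSTS_PER_USER
    female_rate: float = reference.N_FEMALE_USERS / reference.N_GENDERED_USERS
    age_mean: float = reference.MEAN_AGE_YEARS
    age_sd: float = 10.0
    date_start: str = "2014-01"
    date_end: str = "2020-07"
    #: multiplier of Nov–Mar monthly volume relative to Apr–Oct
    seasonal_amplitude: float = 2.0
    n_topics: int = 13
    vocab_size: int = 260
    topic_concentration: float = 5.0
    #: corpus-level topic weights; None → published theme shares when
    #: n_topics == 13, uniform otherwise
    topic_weights: tuple[float, ...] | None = None
    impact_rate: float = reference.IMPACT_RATE
    #: per-category probabilities *conditional on the post bearing ≥1 impact*
    impact_category_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SHARES))
    #: per-post probabilities of each distractor fate
    distractor_rates: dict[str, float] = field(default_factory=lambda: {
        REASON_LANGUAGE: 0.03, REASON_ANIMAL: 0.03,
        REASON_EXCLUSION: 0.02, REASON_NO_INCLUSION: 0.05})
    #: probability a user gets a gendered username (first name)
    gender_marker_rate: float = 0.8
    #: per-post probability of a gendered agreement phrase
    agreement_rate: float = 0.5
    #: probability a user states an explicit age somewhere in their posts
    age_marker_rate: float = 0.5
    source_weights: dict[str, int] = field(
        default_factory=lambda: dict(reference.SOURCE_POSTS))
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.female_rate, self.impact_rate, self.gender_marker_rate,
                 self.agreement_rate, self.age_marker_rate,
                 *self.impact_category_shares.values(),
                 *self.distractor_rates.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must be in [0, 1]")
        if self.n_topics < 1:
            raise ConfigurationError("n_topics must be >= 1")
        if self.vocab_size < 10 * self.n_topics:
            raise ConfigurationError(
                f"vocab_size {self.vocab_size} too small for "
                f"{self.n_topics} topics (need >= 10 per topic)")
        if self.posts_per_user_mean < 1:
            raise ConfigurationError("posts_per_user_mean must be >= 1")
        if sum(self.distractor_rates.values()) >= 1:
            raise ConfigurationError("distractor rates must sum below 1")
        if self.topic_weights is not None and \
                len(self.topic_weights) != self.n_topics:
            raise ConfigurationError("topic_weights length must equal n_topics")

    def resolved_topic_weights(self) -> np.ndarray:
        if self.topic_weights is not None:
            w = np.asarray(self.topic_weights, float)
        elif self.n_topics == len(reference.TOPIC_COUNTS):
            w = np.asarray(list(reference.TOPIC_COUNTS.values()), float)
        else:
            w = np.ones(self.n_topics)
        return w / w.sum()


# -- pseudo-lexicon --------------------------------------------------------

_CONSONANTS = "bdfgjklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


def _blocked_words(lexicons: LexiconSet) -> frozenset[str]:
    from .textnorm import tokenize
    words: set[str] = set()
    lx = lexicons.to_dict()
    for value in lx.values():
        if isinstance(value, list):
            for phrase in value:
                words.update(tokenize(phrase))
        elif isinstance(value, dict):
            for terms in value.values():
                for phrase in terms:
                    words.update(tokenize(phrase))
    return frozenset(words)


def pseudo_vocabulary(size: int,
                      lexicons: LexiconSet | None = None) -> list[str]:
    """Deterministic 3-syllable pseudo-words, disjoint from every lexicon."""
    blocked = _blocked_words(lexicons or default_lexicons())
    n_syl = len(_SYLLABLES)
    words = []
    i = 0
    while len(words) < size:
        w = (_SYLLABLES[i // (n_syl * n_syl) % n_syl]
             + _SYLLABLES[i // n_syl % n_syl] + _SYLLABLES[i % n_syl])
        i += 1
        if w not in blocked:
            words.append(w)
        if i > 10 * size + n_syl ** 3:
            raise ConfigurationError("pseudo-vocabulary exhausted")
    return words


# -- planted topics --------------------------------------------------------

def planted_topic_distributions(K: int, V: int, concentration: float,
                                seed: int,
                                block_mass: float = 0.95) -> np.ndarray:
    """K token-probability vectors, each concentrated on its own token block.

    The vocabulary is partitioned into K disjoint blocks of ⌊V/K⌋ tokens;
    topic k places `block_mass` of its probability on block k (Dirichlet
    weights with the given concentration) and spreads the rest uniformly
    over the other tokens.  Returns an array of shape (K, V), rows sum to 1.
    """
    if V < 10 * K:
        raise ConfigurationError(f"V={V} too small for K={K} (need V >= 10K)")
    rng = np.random.default_rng(seed)
    block = V // K
    phi = np.zeros((K, V))
    for k in range(K):
        lo, hi = k * block, (k + 1) * block
        within = rng.dirichlet(np.full(block, concentration))
        off = V - block
        if off == 0:            # K = 1: all mass inside the single block
            phi[k, lo:hi] = within
        else:
            phi[k, lo:hi] = block_mass * within
            phi[k, :lo] = (1 - block_mass) / off
            phi[k, hi:] = (1 - block_mass) / off
    phi /= phi.sum(axis=1, keepdims=True)
    return phi


def planted_blocks(K: int, V: int) -> list[set[int]]:
    """Token-id block owned by each planted topic."""
    block = V // K
    return [set(range(k * block, (k + 1) * block)) for k in range(K)]


# -- impact label model ----------------------------------------------------

def _base_category_probs(shares: dict[str, float]) -> dict[str, float]:
    """Solve base Bernoulli probabilities so that, after conditioning on
    ≥1 category firing (rejection sampling), the per-category marginals
    equal the requested conditional shares."""
    target = np.array([shares[c] for c in QOL_CATEGORIES])
    p = target.copy()
    for _ in range(50):
        p0 = np.prod(1 - p)
        p_new = np.clip(target * (1 - p0), 0.0, 1.0)
        if np.max(np.abs(p_new - p)) < 1e-12:
            p = p_new
            break
        p = p_new
    return {c: float(p[i]) for i, c in enumerate(QOL_CATEGORIES)}


def _draw_categories(rng: np.random.Generator,
                     base_probs: dict[str, float]) -> list[str]:
    p = np.array([base_probs[c] for c in QOL_CATEGORIES])
    for _ in range(1000):
        draws = rng.random(len(p)) < p
        if draws.any():
            return [c for c, d in zip(QOL_CATEGORIES, draws) if d]
    return [QOL_CATEGORIES[int(np.argmax(p))]]


#: injected per-domain phrases — domain nouns only, chosen so they never
#: collide with gender-agreement adjective forms
_IMPACT_PHRASES = {
    "physical": ["douleurs partout", "une fatigue enorme", "fievre qui dure",
                 "symptomes persistants", "diarrhee depuis des jours"],
    "psychic": ["angoisse permanente", "peur du lendemain", "stress constant",
                "deprime totale", "le desespoir me gagne"],
    "activity": ["arret de travail prolonge", "plus de sport possible",
                 "impossible d'aller au boulot", "conge force"],
    "relational": ["ma famille n'en peut plus", "le couple en souffre",
                   "isolement complet", "mes amis ne comprennent pas"],
    "financial": ["des depenses enormes", "la mutuelle ne rembourse rien",
                  "une facture salee", "plus d'argent pour me soigner"],
}

_INEFFICIENCY_CLAUSES = [
    "ne marchent pas", "ne fonctionnent pas", "ne font pas effet",
    "sont inefficaces", "sont sans effet", "restent inefficaces",
]

_ENGLISH_FILLER = (
    "the treatment is inefficace and it does not work for me at all "
    "because they told me that this was the best they had"
)


# -- generator -------------------------------------------------------------

def _month_table(config: GenerationConfig) -> tuple[pd.PeriodIndex, np.ndarray]:
    months = pd.period_range(config.date_start, config.date_end, freq="M")
    w = np.array([config.seasonal_amplitude if m.month in WINTER_MONTHS
                  else 1.0 for m in months])
    return months, w / w.sum()


def _timestamp(rng: np.random.Generator, month: pd.Period) -> str:
    day = int(rng.integers(1, calendar.monthrange(month.year, month.month)[1] + 1))
    hour = int(rng.integers(0, 24))
    minute = int(rng.integers(0, 60))
    return f"{month.year:04d}-{month.month:02d}-{day:02d}T{hour:02d}:{minute:02d}:00"


def _style_tail(rng: np.random.Generator, age: int) -> tuple[str, int]:
    """Age-dependent style markers (emoticons, exclamations); returns the
    tail string and the number of commas to sprinkle among topic tokens."""
    lam_emo = float(np.clip((55 - age) / 8.0, 0.2, 8.0))
    lam_exc = float(np.clip((50 - age) / 10.0, 0.2, 6.0))
    n_emo = int(rng.poisson(lam_emo))
    n_exc = int(rng.poisson(lam_exc))
    n_commas = int(rng.poisson(age / 12.0))
    tail = " ".join([":)"] * n_emo + ["!"] * n_exc)
    return tail, n_commas


def _topic_clause(rng: np.random.Generator, phi_row: np.ndarray,
                  vocab: list[str], n_tokens: int, n_commas: int) -> str:
    ids = rng.choice(len(vocab), size=n_tokens, p=phi_row)
    words = [vocab[i] for i in ids]
    if n_commas > 0 and len(words) > 1:
        spots = rng.choice(len(words) - 1, size=min(n_commas, len(words) - 1),
                           replace=False)
        for s in spots:
            words[s] = words[s] + ","
    return " ".join(words)


def generate_corpus(config: GenerationConfig,
                    lexicons: LexiconSet | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a post corpus plus its latent ground truth.

    Returns ``(posts, truth)``: posts with columns id/source/timestamp/
    author/text, truth with one row per post carrying the author's latent
    gender and age, the post's true topic (−1 for non-target-language
    distractors), its impact-category set, the fate the filter should assign
    (reason code), and marker-injection flags.  Identical config (including
    seed) reproduces the output byte for byte.
    """
    lexicons = lexicons or default_lexicons()
    rng = np.random.default_rng(config.seed)

    vocab = pseudo_vocabulary(config.vocab_size, lexicons)
    phi = planted_topic_distributions(
        config.n_topics, config.vocab_size, config.topic_concentration,
        seed=int(rng.integers(0, 2 ** 31)))
    topic_w = config.resolved_topic_weights()
    months, month_p = _month_table(config)
    base_cat = _base_category_probs(config.impact_category_shares)

    sources = list(config.source_weights)
    source_p = np.array([config.source_weights[s] for s in sources], float)
    source_p /= source_p.sum()

    d_rates = config.distractor_rates
    d_types = [REASON_LANGUAGE, REASON_ANIMAL, REASON_EXCLUSION,
               REASON_NO_INCLUSION]
    d_cut = np.cumsum([d_rates.get(t, 0.0) for t in d_types])

    posts: list[dict] = []
    truth: list[dict] = []
    post_i = 0

    for u in range(config.n_users):
        gender = "female" if rng.random() < config.female_rate else "male"
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                          10, 100))
        n_posts = 1 + int(rng.poisson(config.posts_per_user_mean - 1))
        source = sources[int(rng.choice(len(sources), p=source_p))]

        has_uname_marker = rng.random() < config.gender_marker_rate
        names = (lexicons.female_names if gender == "female"
                 else lexicons.male_names)
        if has_uname_marker:
            uname = names[int(rng.integers(len(names)))] + \
                str(int(rng.integers(10, 100)))
        else:
            uname = vocab[int(rng.integers(len(vocab)))] + \
                str(int(rng.integers(10, 100)))
        author = f"{uname}_u{u}"

        has_age_marker = rng.random() < config.age_marker_rate
        age_post = int(rng.integers(n_posts)) if has_age_marker else -1
        user_has_agreement = False

        for j in range(n_posts):
            month = months[int(rng.choice(len(months), p=month_p))]
            ts = _timestamp(rng, month)
            r = rng.random()
            fate = REASON_KEPT
            for t, cut in zip(d_types, d_cut):
                if r < cut:
                    fate = t
                    break

            topic = int(rng.choice(config.n_topics, p=topic_w))
            n_tok = max(4, int(round(rng.normal(4 + age / 4.0, 2.0))))
            tail, n_commas = _style_tail(rng, age)
            kw = lexicons.inclusion_keywords[
                int(rng.integers(len(lexicons.inclusion_keywords)))]

            parts: list[str] = []
            has_impact = False
            cats: list[str] = []

            if fate == REASON_LANGUAGE:
                topic = -1
                parts = [f"the {kw} {_ENGLISH_FILLER}"]
            else:
                clause = _INEFFICIENCY_CLAUSES[
                    int(rng.integers(len(_INEFFICIENCY_CLAUSES)))]
                if fate == REASON_NO_INCLUSION:
                    parts.append(f"les {kw} prescrits hier par le medecin")
                else:
                    parts.append(f"les {kw} {clause}")
                if fate == REASON_ANIMAL:
                    animal = lexicons.animal_vocabulary[
                        int(rng.integers(len(lexicons.animal_vocabulary)))]
                    parts.append(f"pour mon {animal} malade")
                elif fate == REASON_EXCLUSION:
                    word = lexicons.exclusion_words[
                        int(rng.integers(len(lexicons.exclusion_words)))]
                    parts.append(f"voir le {word} en ligne")

                parts.append(_topic_clause(rng, phi[topic], vocab,
                                           n_tok, n_commas))

                if fate == REASON_KEPT:
                    if rng.random() < config.agreement_rate:
                        agr = (lexicons.female_agreements if gender == "female"
                               else lexicons.male_agreements)
                        parts.append("je suis " +
                                     agr[int(rng.integers(len(agr)))])
                        user_has_agreement = True
                    if rng.random() < 0.15:
                        fld = (lexicons.female_field if gender == "female"
                               else lexicons.male_field)
                        parts.append(fld[int(rng.integers(len(fld)))])
                        user_has_agreement = True
                    if j == age_post:
                        if rng.random() < 0.5:
                            parts.append(f"j'ai {age} ans")
                        else:
                            born = int(ts[:4]) - age
                            nee = "née" if gender == "female" else "né"
                            parts.append(f"je suis {nee} en {born}")
                    has_impact = rng.random() < config.impact_rate
                    if has_impact:
                        cats = _draw_categories(rng, base_cat)
                        for c in cats:
                            opts = _IMPACT_PHRASES[c]
                            parts.append(opts[int(rng.integers(len(opts)))])
                        if rng.random() < 0.6:
                            neg = lexicons.sentiment_negative
                            parts.append("c'est " +
                                         neg[int(rng.integers(len(neg)))])
                    elif rng.random() < 0.3:
                        pos = lexicons.sentiment_positive
                        parts.append(pos[int(rng.integers(len(pos)))])

            if tail and fate != REASON_LANGUAGE:
                parts.append(tail)

            posts.append({"id": f"p{post_i:07d}", "source": source,
                          "timestamp": ts, "author": author,
                          "text": " ".join(parts)})
            truth.append({
                "post_id": f"p{post_i:07d}", "user_id": f"u{u}",
                "author": author, "true_gender": gender, "true_age": age,
                "true_topic": topic, "has_impact": has_impact,
                "impact_categories": "|".join(cats),
                "filter_reason": fate,
                "has_gender_marker": bool(has_uname_marker),
                "has_age_marker": bool(has_age_marker),
            })
            post_i += 1

        # username markers count for the user as a whole; agreements were
        # decided per post, so patch the user's rows afterwards
        if user_has_agreement and not has_uname_marker:
            for row in truth[-n_posts:]:
                row["has_gender_marker"] = True

    posts_df = pd.DataFrame(posts)
    truth_df = pd.DataFrame(truth)
    return posts_df, truth_df


def generate_topic_corpus(n_docs: int, K: int, V: int, doc_len: int = 12,
                          concentration: float = 5.0, seed: int = 0,
                          ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Bare planted-topic documents for topic-recovery experiments.

    Returns (texts, labels, phi): pseudo-word documents of `doc_len` tokens
    each drawn from one planted topic (uniform topic choice), the true
    topic labels, and the planted topic-word matrix (K × V).
    """
    rng = np.random.default_rng(seed)
    vocab = pseudo_vocabulary(V)
    phi = planted_topic_distributions(K, V, concentration,
                                      seed=int(rng.integers(0, 2 ** 31)))
    labels = rng.integers(0, K, size=n_docs)
    texts = []
    for k in labels:
        ids = rng.choice(V, size=doc_len, p=phi[k])
        texts.append(" ".join(vocab[i] for i in ids))
    return texts, labels, phi


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
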