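"""Corpus inclusion rule and exclusion cascade.

A message enters the analysis corpus when it mentions an antibiotic keyword
(or synonym) *and* an inefficiency lexical field within the same message.
Included messages then pass an exclusion cascade applied in a fixed order —
non-target language, animal-related vocabulary, study-specific exclusion
words — with each removal attributed to the first rule that fires, so the
audit report always balances exactly.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, asdict

import pandas as pd

from .lexicons import LexiconSet
from .textnorm import fold, tokenize, any_match

# Reason codes attributed to each post; KEPT marks survivors.
REASON_KEPT = "KEPT"
REASON_NO_INCLUSION = "NO_INCLUSION_MATCH"
REASON_LANGUAGE = "NON_TARGET_LANGUAGE"
REASON_ANIMAL = "ANIMAL_VOCABULARY"
REASON_EXCLUSION = "EXCLUSION_WORD"
REASON_CODES = (REASON_KEPT, REASON_NO_INCLUSION, REASON_LANGUAGE,
                REASON_ANIMAL, REASON_EXCLUSION)

# Negated-efficacy construction: "ne <up to 5 words> pas" with an efficacy
# verb stem inside the gap ("les antibiotiques ne marchent pas").
_NEG_GAP = re.compile(r"(?<![a-z])ne((?:[^a-z]+[a-z]+){1,5})[^a-z]+pas(?![a-z])")
_EFFICACY_STEMS = ("march", "fonctionn", "agit", "agiss", "guerit",
                   "gueriss", "soign", "soulag", "fait", "font")

_MIN_TOKENS_FOR_LANGUAGE = 3

LANG_UNDETERMINED = "undetermined"


@dataclass
class FilterReport:
    """Audit of one filtering run; input = output + sum(removed)."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {
        REASON_NO_INCLUSION: 0, REASON_LANGUAGE: 0,
        REASON_ANIMAL: 0, REASON_EXCLUSION: 0})
    n_output: int = 0

    def balances(self) -> bool:
        return self.n_input == self.n_output + sum(self.removed.values())

    def to_dict(self) -> dict:
        return asdict(self)


def _negated_efficacy(folded: str) -> bool:
    for m in _NEG_GAP.finditer(folded):
        gap_words = re.findall(r"[a-z]+", m.group(1))
        if any(w.startswith(_EFFICACY_STEMS) for w in gap_words):
            return True
    return False


def matches_inclusion(text: str, lexicons: LexiconSet) -> bool:
    """True iff a keyword and an inefficiency-field phrase co-occur in `text`.

    Both are matched case- and accent-insensitively on token boundaries; the
    inefficiency field also covers "ne ... pas" negations of efficacy verbs
    with a 5-token gap limit.
    """
    folded = fold(text)
    if not any_match(folded, lexicons.inclusion_patterns):
        return False
    return (any_match(folded, lexicons.inefficiency_patterns)
            or _negated_efficacy(folded))


def detect_language(text: str, lexicons: LexiconSet) -> str:
    """Stopword-profile language tag, or "undetermined" for very short text.

    Each configured profile scores the count of its stopwords among the
    message tokens; the top-scoring profile wins, ties (including all-zero)
    are "undetermined".  Undetermined posts are *kept* by the cascade.
    """
    tokens = tokenize(text)
    if len(tokens) < _MIN_TOKENS_FOR_LANGUAGE:
        return LANG_UNDETERMINED
    scores = {tag: sum(t in words for t in tokens)
              for tag, words in lexicons.stopword_sets.items()}
    best = max(scores.values(), default=0)
    winners = [tag for tag, s in scores.items() if s == best]
    if best == 0 or len(winners) != 1:
        return LANG_UNDETERMINED
    return winners[0]


def exclusion_reason(text: str, lexicons: LexiconSet) -> str | None:
    """First exclusion rule fired by `text` (fixed order), or None."""
    lang = detect_language(text, lexicons)
    if lang not in (lexicons.target_language, LANG_UNDETERMINED):
        return REASON_LANGUAGE
    folded = fold(text)
    if any_match(folded, lexicons.animal_patterns):
        return REASON_ANIMAL
    if any_match(folded, lexicons.exclusion_patterns):
        return REASON_EXCLUSION
    return None


def apply_exclusions(posts: pd.DataFrame,
                     lexicons: LexiconSet) -> tuple[pd.DataFrame, FilterReport]:
    """Run the exclusion cascade over an already-included corpus.

    Rules fire in the fixed order language → animal vocabulary → exclusion
    word; each removed post is attributed to the first rule that fires.
    """
    report = FilterReport(n_input=len(posts))
    keep_mask = []
    for text in posts["text"]:
        reason = exclusion_reason(text, lexicons)
        if reason is None:
            keep_mask.append(True)
        else:
            keep_mask.append(False)
            report.removed[reason] += 1
    kept = posts.loc[keep_mask].reset_index(drop=True)
    report.n_output = len(kept)
    return kept, report


def filter_corpus(posts: pd.DataFrame,
                  lexicons: LexiconSet) -> tuple[pd.DataFrame, FilterReport]:
    """Full pipeline: inclusion rule, then the exclusion cascade."""
    included_mask = posts["text"].map(
        lambda t: matches_inclusion(t, lexicons)).to_numpy()
    included = posts.loc[included_mask].reset_index(drop=True)
    kept, report = apply_exclusions(included, lexicons)
    report.n_input = len(posts)
    report.removed[REASON_NO_INCLUSION] = int((~included_mask).sum())
    return kept, report


def post_reason(text: str, lexicons: LexiconSet) -> str:
    """Reason code the full filter assigns to one message."""
    if not matches_inclusion(text, lexicons):
        return REASON_NO_INCLUSION
    return exclusion_reason(text, lexicons) or REASON_KEPT


# -- anonymization --------------------------------------------------------

_HASH_RE = re.compile(r"^u:[0-9a-f]{16}$")
_HANDLE_RE = re.compile(r"(?<!\w)@\w+")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+")


def _hash_author(author: str, salt: str) -> str:
    digest = hashlib.sha256((salt + ":" + author).encode()).hexdigest()[:16]
    return f"u:{digest}"


def anonymize_text(text: str) -> str:
    return _URL_RE.sub("<URL>", _HANDLE_RE.sub("<USER>", text))


def anonymize(post: dict, salt: str) -> dict:
    """Replace the author by a keyed one-way hash and scrub handles/URLs.

    Idempotent: an already-hashed author (``u:<16 hex>``) is left alone, and
    the placeholder tokens contain nothing the scrub patterns match.
    """
    author = post["author"]
    if not _HASH_RE.match(author):
        author = _hash_author(author, salt)
    out = dict(post)
    out["author"] = author
    out["text"] = anonymize_text(post["text"])
    return out


def anonymize_corpus(posts: pd.DataFrame, salt: str) -> pd.DataFrame:
    out = posts.copy()
    out["author"] = [a if _HASH_RE.match(a) else _hash_author(a, salt)
                     for a in out["author"]]
    out["text"] = out["text"].map(anonymize_text)
    return out
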