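"""Text normalization shared by every stage of the pipeline.

Forum text in French mixes cases, diacritics and typographic apostrophes
freely ("Antibiotique", "antibiotiqué", "J’AI"), so all lexicon matching is
done on lowercased, accent-folded text with token-boundary anchoring.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache

_APOSTROPHES = str.maketrans({"’": "'", "ʼ": "'", "`": "'"})

_WORD_RE = re.compile(r"[a-z]+")


def fold(text: str) -> str:
    """Lowercase and strip diacritics (NFKD decomposition, drop combining marks)."""
    text = text.translate(_APOSTROPHES).lower()
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def tokenize(text: str) -> list[str]:
    """Alphabetic tokens of folded text (digits and punctuation are separators)."""
    return _WORD_RE.findall(fold(text))


@lru_cache(maxsize=4096)
def phrase_pattern(phrase: str) -> re.Pattern[str]:
    """Compile a folded phrase into a token-boundary-anchored regex.

    Multi-word phrases tolerate any non-letter run between words, so
    "ne marche pas" matches "ne  marche , pas".
    """
    words = tokenize(phrase)
    if not words:
        raise ValueError(f"phrase has no alphabetic content: {phrase!r}")
    body = r"[^a-z]+".join(re.escape(w) for w in words)
    return re.compile(rf"(?<![a-z]){body}(?![a-z])")


def count_matches(folded_text: str, patterns: list[re.Pattern[str]]) -> int:
    return sum(len(p.findall(folded_text)) for p in patterns)


def any_match(folded_text: str, patterns: list[re.Pattern[str]]) -> bool:
    return any(p.search(folded_text) for p in patterns)
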