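"""Lexicon configuration driving every rule-based stage.

A single :class:`LexiconSet` bundles all the word lists and phrase families
used by corpus inclusion/exclusion, language profiling, gender and age
inference, sentiment features and the five health-related quality-of-life
(HRQoL) domains (physical, psychic, activity, relational, financial).

The default set is a compact, curated French lexicon sufficient to drive the
pipeline and its synthetic corpora.  The study-specific exclusion-word list
used for the original corpus is not public; the default here is a documented
placeholder and any list can be substituted via JSON (:func:`load_lexicons`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from functools import cached_property
from pathlib import Path

from .textnorm import fold, phrase_pattern

QOL_CATEGORIES = ("physical", "psychic", "activity", "relational", "financial")


@dataclass
class LexiconSet:
    """All word lists / regex families used by the pipeline.

    Every list is matched case- and accent-insensitively on token
    boundaries; multi-word entries tolerate arbitrary punctuation between
    words.
    """

    inclusion_keywords: list[str]
    inefficiency_field: list[str]
    exclusion_words: list[str]
    animal_vocabulary: list[str]
    target_language: str = "fr"
    # stopword profiles for language detection, keyed by language tag
    stopword_profiles: dict[str, list[str]] = field(default_factory=dict)
    # demographics
    female_names: list[str] = field(default_factory=list)
    male_names: list[str] = field(default_factory=list)
    female_suffixes: list[str] = field(default_factory=list)
    male_suffixes: list[str] = field(default_factory=list)
    female_field: list[str] = field(default_factory=list)
    male_field: list[str] = field(default_factory=list)
    female_agreements: list[str] = field(default_factory=list)
    male_agreements: list[str] = field(default_factory=list)
    # sentiment + QoL domains
    sentiment_positive: list[str] = field(default_factory=list)
    sentiment_negative: list[str] = field(default_factory=list)
    qol_domains: dict[str, list[str]] = field(default_factory=dict)
    # tokens ignored by topic-model preprocessing
    topic_stopwords: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.inclusion_keywords:
            raise ValueError("inclusion_keywords must be non-empty")
        if not self.inefficiency_field:
            raise ValueError("inefficiency_field must be non-empty")
        # every pattern must compile; phrase_pattern raises on empty phrases
        for name in ("inclusion_keywords", "inefficiency_field",
                     "exclusion_words", "animal_vocabulary"):
            for phrase in getattr(self, name):
                phrase_pattern(phrase)

    # -- compiled pattern caches ------------------------------------------

    @cached_property
    def inclusion_patterns(self) -> list[re.Pattern[str]]:
        return [phrase_pattern(p) for p in self.inclusion_keywords]

    @cached_property
    def inefficiency_patterns(self) -> list[re.Pattern[str]]:
        return [phrase_pattern(p) for p in self.inefficiency_field]

    @cached_property
    def exclusion_patterns(self) -> list[re.Pattern[str]]:
        return [phrase_pattern(p) for p in self.exclusion_words]

    @cached_property
    def animal_patterns(self) -> list[re.Pattern[str]]:
        return [phrase_pattern(p) for p in self.animal_vocabulary]

    @cached_property
    def domain_patterns(self) -> dict[str, list[re.Pattern[str]]]:
        return {d: [phrase_pattern(p) for p in terms]
                for d, terms in self.qol_domains.items()}

    @cached_property
    def stopword_sets(self) -> dict[str, frozenset[str]]:
        return {tag: frozenset(fold(w) for w in words)
                for tag, words in self.stopword_profiles.items()}

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LexiconSet":
        return cls(**d)


def save_lexicons(lexicons: LexiconSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(lexicons.to_dict(), ensure_ascii=False,
                                     indent=1))


def load_lexicons(path: str | Path) -> LexiconSet:
    return LexiconSet.from_dict(json.loads(Path(path).read_text()))


# French stopwords shared between language profiling and topic preprocessing.
# Words also common in English ("a", "la" in lyrics, ...) are kept out of the
# *profiles* so the two language signatures stay disjoint.
_FR_STOP = [
    "le", "les", "de", "des", "du", "un", "une", "et", "est", "je",
    "ne", "pas", "que", "qui", "dans", "pour", "sur", "avec", "mais",
    "mon", "ma", "mes", "ce", "cette", "il", "elle", "nous", "vous",
    "suis", "ai", "au", "aux", "plus", "tres", "bien", "tout", "fait",
    "chez", "depuis", "rien", "sont", "ans", "son", "sa", "ses", "en",
]
_EN_STOP = [
    "the", "and", "of", "to", "is", "it", "that", "for", "with", "was",
    "not", "this", "but", "are", "have", "they", "you", "what", "all",
    "does", "work", "because", "any", "been", "from", "had", "has", "at",
    "my", "me", "i", "we", "about", "there", "when", "will", "can",
]


def default_lexicons() -> LexiconSet:
    """The built-in French lexicon set.

    Curated to cover antibiotic-class keywords, the inefficiency lexical
    field, the exclusion cascade, gender/age markers and the five HRQoL
    domains.  Gender-agreement forms are chosen so that masculine forms do
    not collide with domain nouns once accents are folded (e.g. "fatigué" →
    "fatigue" would shadow the physical-domain noun, so it is not an
    agreement marker).
    """
    return LexiconSet(
        inclusion_keywords=[
            "antibiotique", "antibiotiques", "antibio", "antibios",
            "amoxicilline", "augmentin", "penicilline", "azithromycine",
            "ciprofloxacine", "antibiotherapie",
        ],
        inefficiency_field=[
            "inefficace", "inefficaces", "inefficacite",
            "sans effet", "aucun effet", "aucune amelioration",
            "pas d'amelioration", "toujours malade", "toujours pas guerie",
            "toujours pas gueri", "resistant au traitement",
            "resistance au traitement", "echec du traitement",
        ],
        exclusion_words=[
            # placeholder for the study-specific list (not public); swap via
            # a JSON lexicon file to replicate any particular filtering
            "concours", "promotion", "publicite", "gagnez", "cliquez",
        ],
        animal_vocabulary=[
            "chien", "chienne", "chiot", "chat", "chaton", "cheval",
            "lapin", "hamster", "perroquet", "veterinaire", "veto",
        ],
        target_language="fr",
        stopword_profiles={"fr": _FR_STOP, "en": _EN_STOP},
        female_names=[
            "marie", "sophie", "julie", "camille", "emma", "lea", "chloe",
            "laura", "sarah", "manon", "claire", "lucie", "nathalie",
            "isabelle", "celine",
        ],
        male_names=[
            "pierre", "jean", "paul", "thomas", "nicolas", "julien",
            "antoine", "hugo", "louis", "maxime", "lucas", "romain",
            "david", "olivier", "marc",
        ],
        female_suffixes=["ette", "elle", "ine", "ia"],
        male_suffixes=["eau", "ien", "ot"],
        female_field=[
            "mon mari", "mon copain", "enceinte", "ma grossesse",
            "gyneco", "mes regles",
        ],
        male_field=[
            "ma femme", "ma copine", "ma barbe", "prostate",
        ],
        female_agreements=[
            "allee", "inquiete", "contente", "heureuse", "decue", "seule",
            "desesperee", "epuisee", "soulagee", "partie", "prete",
        ],
        male_agreements=[
            "alle", "inquiet", "content", "heureux", "decu", "seul",
            "desespere", "soulage", "parti", "pret",
        ],
        sentiment_positive=[
            "merci", "super", "mieux", "gueri", "guerie", "soulagement",
            "espoir", "efficace", "parfait", "genial",
        ],
        sentiment_negative=[
            "marre", "horrible", "terrible", "pire", "souffre", "souffrance",
            "insupportable", "inquietant", "grave", "catastrophe",
        ],
        qol_domains={
            "physical": [
                "douleur", "douleurs", "fatigue", "epuisee", "epuise",
                "fievre", "symptomes", "symptome", "diarrhee", "vomissements",
                "insomnie", "migraine",
            ],
            "psychic": [
                "angoisse", "angoissee", "peur", "stress", "deprime",
                "depression", "desespoir", "moral a zero", "anxiete",
            ],
            "activity": [
                "arret de travail", "arret maladie", "travail", "boulot",
                "sport", "activites", "conge",
            ],
            "relational": [
                "famille", "couple", "isolement", "isolee", "isole",
                "amis", "sexualite", "vie sociale",
            ],
            "financial": [
                "cout", "couteux", "rembourse", "remboursement", "mutuelle",
                "depenses", "argent", "euros", "facture",
            ],
        },
        topic_stopwords=_FR_STOP + [
            "ils", "elles", "ont", "etre", "avoir", "cela", "comme", "meme",
            "aussi", "donc", "alors", "quand", "sans", "sous", "votre",
            "notre", "leur", "leurs", "moi", "toi", "lui", "être",
        ],
    )
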