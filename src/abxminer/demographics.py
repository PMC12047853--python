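"""User attribute inference: scored gender prediction and two-stage age.

Gender: evidence items (first name or gendered affix in the username,
gender-specific lexical fields and gendered adjective/participle agreements
in the message content) each add a configured weight to a per-gender score;
the prediction is the argmax, with ties mapped to "unknown".

Age: regular expressions over all of a user's posts ("j'ai 34 ans",
"née en 1985" with year arithmetic) take precedence; users without an
explicit age expression fall back to a gradient-boosted regression model
over stylometric features (message length, punctuation and emoticon rates,
sentiment hits, source), with quantile companion models providing a
prediction interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .lexicons import LexiconSet
from .textnorm import fold, tokenize, phrase_pattern

AGE_MIN, AGE_MAX = 10, 100

#: evidence weights — a first name in the username is the strongest signal
WEIGHT_USERNAME_NAME = 3.0
WEIGHT_USERNAME_AFFIX = 1.0
WEIGHT_FIELD = 1.0
WEIGHT_AGREEMENT = 1.0


@dataclass
class UserProfile:
    user_id: str
    gender: str                      # "female" | "male" | "unknown"
    female_score: float
    male_score: float
    age: float | None
    age_method: str                  # "regex" | "model" | "none"


# -- gender ----------------------------------------------------------------

def _username_alpha_runs(username: str) -> list[str]:
    return re.findall(r"[a-z]+", fold(username))


def score_gender(username: str, texts: list[str],
                 lexicons: LexiconSet) -> tuple[float, float]:
    """(female score, male score): additive over evidence items.

    Scores are sums of nonnegative weights, so they are permutation-
    invariant over posts and monotone non-decreasing as posts are added.
    """
    female = male = 0.0
    runs = _username_alpha_runs(username)
    name_sets = (set(lexicons.female_names), set(lexicons.male_names))
    for run in runs:
        if run in name_sets[0]:
            female += WEIGHT_USERNAME_NAME
        if run in name_sets[1]:
            male += WEIGHT_USERNAME_NAME
    for run in runs:
        if run in name_sets[0] or run in name_sets[1]:
            continue  # a full name already counted; affixes are weaker cues
        if any(run.endswith(s) for s in lexicons.female_suffixes):
            female += WEIGHT_USERNAME_AFFIX
        elif any(run.endswith(s) for s in lexicons.male_suffixes):
            male += WEIGHT_USERNAME_AFFIX

    fem_field = [phrase_pattern(p) for p in lexicons.female_field]
    mal_field = [phrase_pattern(p) for p in lexicons.male_field]
    fem_agree = set(lexicons.female_agreements)
    mal_agree = set(lexicons.male_agreements)
    for text in texts:
        folded = fold(text)
        female += WEIGHT_FIELD * sum(len(p.findall(folded)) for p in fem_field)
        male += WEIGHT_FIELD * sum(len(p.findall(folded)) for p in mal_field)
        for tok in tokenize(text):
            if tok in fem_agree:
                female += WEIGHT_AGREEMENT
            elif tok in mal_agree:
                male += WEIGHT_AGREEMENT
    return female, male


def predict_gender(female_score: float, male_score: float) -> str:
    if female_score > male_score:
        return "female"
    if male_score > female_score:
        return "male"
    return "unknown"


# -- age: regular expressions ---------------------------------------------

# "j'ai 34 ans" (apostrophe variants tolerated)
_AGE_JAI = re.compile(r"\bj\s*'?\s*ai\s+(\d{1,3})\s+ans\b")
# bare "34 ans", guarded against durations ("pris 3 ans de traitement")
_AGE_BARE = re.compile(r"(?<![\d'])\b(\d{1,3})\s+ans\b")
_BARE_GUARDS = frozenset({
    "pris", "depuis", "pendant", "dans", "apres", "avant", "a", "y",
    "durant", "pour", "les", "des", "ces", "mes", "ses",
})
# "née en 1985" / "né en 1985"; bare "ne" (negation) must not fire
_AGE_BORN = re.compile(r"\b(?:née|nee|né)\s+en\s+((?:19|20)\d{2})\b")


def _bare_age_candidates(folded: str) -> list[int]:
    out = []
    for m in _AGE_BARE.finditer(folded):
        prefix = folded[:m.start()]
        words = re.findall(r"[a-z]+", prefix)
        if words and words[-1] in _BARE_GUARDS:
            continue
        out.append(int(m.group(1)))
    return out


def extract_age_regex(posts: pd.DataFrame) -> int | None:
    """Explicit age from a user's posts, or None.

    Candidates from "j'ai N ans", guarded bare "N ans" and "né(e) en YYYY"
    (converted with the post's timestamp year) are restricted to [10, 100];
    conflicts are resolved by majority, then by the most recent post.
    """
    candidates: list[tuple[int, str]] = []  # (age, timestamp)
    for _, row in posts.iterrows():
        text = str(row["text"]).lower().replace("’", "'")
        ts = str(row["timestamp"])
        folded = fold(text)
        ages = [int(m.group(1)) for m in _AGE_JAI.finditer(folded)]
        ages += _bare_age_candidates(folded)
        for m in _AGE_BORN.finditer(text):
            year = int(m.group(1))
            post_year = int(ts[:4])
            ages.append(post_year - year)
        for a in ages:
            if AGE_MIN <= a <= AGE_MAX:
                candidates.append((a, ts))
    if not candidates:
        return None
    counts: dict[int, int] = {}
    for a, _ in candidates:
        counts[a] = counts.get(a, 0) + 1
    top = max(counts.values())
    tied = {a for a, c in counts.items() if c == top}
    if len(tied) == 1:
        return tied.pop()
    for a, _ in sorted(candidates, key=lambda t: t[1], reverse=True):
        if a in tied:
            return a
    return None  # unreachable


# -- age: model fallback ---------------------------------------------------

_EMOTICON_RE = re.compile(r"[:;]-?[)(dpDP]")

AGE_FEATURE_NAMES = [
    "mean_tokens", "max_tokens", "n_posts", "emoticons_per_post",
    "exclaims_per_post", "commas_per_token", "sentiment_pos_per_post",
    "sentiment_neg_per_post",
]


def age_features(posts: pd.DataFrame, lexicons: LexiconSet,
                 sources: list[str]) -> np.ndarray:
    """Stylometric feature vector for one user (+ source one-hot)."""
    texts = [str(t) for t in posts["text"]]
    n = max(len(texts), 1)
    tok_counts = [len(tokenize(t)) for t in texts] or [0]
    total_tokens = max(sum(tok_counts), 1)
    emoticons = sum(len(_EMOTICON_RE.findall(t)) for t in texts)
    exclaims = sum(t.count("!") for t in texts)
    commas = sum(t.count(",") for t in texts)
    pos_pat = [phrase_pattern(p) for p in lexicons.sentiment_positive]
    neg_pat = [phrase_pattern(p) for p in lexicons.sentiment_negative]
    pos = sum(len(p.findall(fold(t))) for t in texts for p in pos_pat)
    neg = sum(len(p.findall(fold(t))) for t in texts for p in neg_pat)
    base = [float(np.mean(tok_counts)), float(np.max(tok_counts)), float(n),
            emoticons / n, exclaims / n, commas / total_tokens,
            pos / n, neg / n]
    src = posts["source"].mode().iat[0] if len(posts) else ""
    onehot = [1.0 if src == s else 0.0 for s in sources]
    return np.array(base + onehot)


class AgeModel:
    """Gradient-boosted age regressor with quantile prediction intervals."""

    def __init__(self, seed: int = 0, interval: tuple[float, float] = (0.1, 0.9)):
        self.seed = seed
        self.interval = interval
        self.sources: list[str] = []
        self._mean = None
        self._lo = None
        self._hi = None

    @property
    def is_fitted(self) -> bool:
        return self._mean is not None

    def fit(self, X: np.ndarray, ages: np.ndarray) -> "AgeModel":
        kw = dict(n_estimators=200, max_depth=3, random_state=self.seed)
        self._mean = GradientBoostingRegressor(**kw).fit(X, ages)
        self._lo = GradientBoostingRegressor(
            loss="quantile", alpha=self.interval[0], **kw).fit(X, ages)
        self._hi = GradientBoostingRegressor(
            loss="quantile", alpha=self.interval[1], **kw).fit(X, ages)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("AgeModel is not trained; call fit() first")
        return np.clip(self._mean.predict(np.atleast_2d(X)), AGE_MIN, AGE_MAX)

    def predict_interval(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("AgeModel is not trained; call fit() first")
        X = np.atleast_2d(X)
        lo = np.clip(self._lo.predict(X), AGE_MIN, AGE_MAX)
        hi = np.clip(self._hi.predict(X), AGE_MIN, AGE_MAX)
        return np.column_stack([lo, hi])


def train_age_model(posts: pd.DataFrame, user_ages: dict[str, float],
                    lexicons: LexiconSet, seed: int = 0) -> AgeModel:
    """Fit the fallback model from per-user post groups and known ages."""
    sources = sorted(posts["source"].unique())
    model = AgeModel(seed=seed)
    model.sources = sources
    rows, ages = [], []
    for uid, grp in posts.groupby("author", sort=True):
        if uid in user_ages:
            rows.append(age_features(grp, lexicons, sources))
            ages.append(user_ages[uid])
    model.fit(np.vstack(rows), np.asarray(ages, float))
    return model


def predict_age(posts: pd.DataFrame, lexicons: LexiconSet,
                model: AgeModel | None = None) -> tuple[float | None, str]:
    """Two-stage dispatch: regex first, model fallback only on no match."""
    age = extract_age_regex(posts)
    if age is not None:
        return float(age), "regex"
    if model is None:
        return None, "none"
    x = age_features(posts, lexicons, model.sources)
    return float(model.predict(x)[0]), "model"


def build_profiles(posts: pd.DataFrame, lexicons: LexiconSet,
                   model: AgeModel | None = None) -> pd.DataFrame:
    """One UserProfile row per author in the corpus."""
    rows = []
    for author, grp in posts.groupby("author", sort=True):
        f, m = score_gender(author, list(grp["text"]), lexicons)
        age, method = predict_age(grp, lexicons, model)
        rows.append({"user_id": author, "gender": predict_gender(f, m),
                     "female_score": f, "male_score": m,
                     "age": age, "age_method": method})
    return pd.DataFrame(rows)
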