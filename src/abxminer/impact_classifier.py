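"""Two-stage quality-of-life impact classification.

Stage 1, the *impact gate*, is a binary gradient-boosted classifier
deciding whether a message expresses any health-related quality-of-life
impact.  Stage 2 is five one-vs-rest gradient-boosted models — physical,
psychic, activity, relational, financial — evaluated only when the gate
fires, so a message may carry several categories (or, below the gate
threshold, none).  All six models share one feature extractor over
sentiment, grammar, conjugation and per-domain lexical-field counts.

The original study's annotated training corpus is not available; the
architecture here is trained on synthetic annotated posts, and the feature
schema, gating contract and reporting conventions are the reproduced
object, not any particular set of weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .lexicons import LexiconSet, QOL_CATEGORIES
from .textnorm import fold, tokenize, phrase_pattern

_FIRST_PERSON = frozenset({"je", "j", "me", "moi", "mon", "ma", "mes"})
_NEGATION = frozenset({"ne", "pas", "plus", "jamais", "rien",
                       "aucun", "aucune"})
_PRESENT = frozenset({"est", "suis", "sont", "fait", "font", "vais",
                      "marche", "marchent", "peut", "peuvent"})
_PAST_WORDS = frozenset({"hier", "avant", "autrefois"})

#: fixed feature ordering shared by all six models
FEATURE_NAMES = (
    ["sentiment_pos", "sentiment_neg", "first_person", "tense_past",
     "tense_present", "tense_conditional", "negation"]
    + [f"qol_{c}" for c in QOL_CATEGORIES]
    + ["n_tokens"]
)

DEFAULT_THRESHOLD = 0.5
_FORMAT_VERSION = 1


def extract_features(text: str, lexicons: LexiconSet) -> np.ndarray:
    """Count-feature vector in the fixed FEATURE_NAMES order.

    All components are nonnegative counts, additive over (space-joined)
    text concatenation.  Conjugation is approximated lexically: imparfait/
    conditional by verb endings, present and past by small marker sets.
    """
    folded = fold(text)
    toks = tokenize(text)
    pos = sum(len(phrase_pattern(w).findall(folded))
              for w in lexicons.sentiment_positive)
    neg = sum(len(phrase_pattern(w).findall(folded))
              for w in lexicons.sentiment_negative)
    first = sum(t in _FIRST_PERSON for t in toks)
    past = sum(t.endswith(("ais", "ait", "aient")) or t in _PAST_WORDS
               for t in toks)
    present = sum(t in _PRESENT for t in toks)
    cond = sum(t.endswith(("rais", "rait", "raient")) for t in toks)
    negation = sum(t in _NEGATION for t in toks)
    domains = [sum(len(p.findall(folded)) for p in lexicons.domain_patterns[c])
               for c in QOL_CATEGORIES]
    vec = np.array([pos, neg, first, past, present, cond, negation,
                    *domains, len(toks)], dtype=float)
    return vec


def feature_matrix(texts: list[str], lexicons: LexiconSet) -> np.ndarray:
    return np.vstack([extract_features(t, lexicons) for t in texts])


@dataclass
class ImpactPrediction:
    """Gate decision plus per-category flags for one message."""

    has_impact: bool
    impact_probability: float
    #: per-category probabilities; empty whenever the gate is negative
    category_probabilities: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def categories(self) -> list[str]:
        if not self.has_impact:
            return []
        return [c for c, p in self.category_probabilities.items()
                if p >= self.threshold]


@dataclass
class ImpactModelBundle:
    """One gate model + five one-vs-rest category models."""

    gate: XGBClassifier
    categories: dict[str, XGBClassifier]
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0


def _make_model(seed: int) -> XGBClassifier:
    return XGBClassifier(n_estimators=200, max_depth=4, learning_rate=0.1,
                         random_state=seed, n_jobs=1, verbosity=0,
                         eval_metric="logloss")


def train(texts: list[str], has_impact: np.ndarray,
          category_labels: pd.DataFrame, lexicons: LexiconSet,
          seed: int = 0,
          threshold: float = DEFAULT_THRESHOLD) -> ImpactModelBundle:
    """Fit the gate on all posts and each category model on the
    impact-positive posts only.  Training is seed-reproducible.

    `category_labels` has one boolean column per QoL category, aligned with
    `texts`; rows where `has_impact` is false are ignored by stage 2.
    """
    X = feature_matrix(texts, lexicons)
    y = np.asarray(has_impact, bool)
    if len(np.unique(y)) < 2:
        raise ValueError("gate model target has a single class")
    gate = _make_model(seed).fit(X, y.astype(int))
    pos = y
    models = {}
    for i, c in enumerate(QOL_CATEGORIES):
        yc = np.asarray(category_labels[c], bool)[pos]
        if len(np.unique(yc)) < 2:
            raise ValueError(f"category model '{c}' target has a single class")
        models[c] = _make_model(seed + 1 + i).fit(X[pos], yc.astype(int))
    return ImpactModelBundle(gate=gate, categories=models,
                             threshold=threshold, seed=seed)


def classify(text: str, bundle: ImpactModelBundle,
             lexicons: LexiconSet) -> ImpactPrediction:
    """Gate first; stage-2 category models run only when the gate fires."""
    x = extract_features(text, lexicons)[None, :]
    p_gate = float(bundle.gate.predict_proba(x)[0, 1])
    if p_gate < bundle.threshold:
        return ImpactPrediction(False, p_gate, {}, bundle.threshold)
    cat_probs = {c: float(m.predict_proba(x)[0, 1])
                 for c, m in bundle.categories.items()}
    return ImpactPrediction(True, p_gate, cat_probs, bundle.threshold)


def classify_corpus(posts: pd.DataFrame, bundle: ImpactModelBundle,
                    lexicons: LexiconSet) -> pd.DataFrame:
    """Predictions as a frame: post id, gate prob, 5 category probs, flags."""
    X = feature_matrix(list(posts["text"]), lexicons)
    p_gate = bundle.gate.predict_proba(X)[:, 1]
    fired = p_gate >= bundle.threshold
    out = pd.DataFrame({"id": posts["id"].to_numpy(),
                        "impact_probability": p_gate,
                        "has_impact": fired})
    for c, m in bundle.categories.items():
        probs = np.zeros(len(posts))
        if fired.any():
            probs[fired] = m.predict_proba(X[fired])[:, 1]
        # gating contract: no category on a gate-negative post
        out[f"p_{c}"] = probs
        out[c] = fired & (probs >= bundle.threshold)
    return out


def impact_summary(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-category counts under both published percentage conventions.

    (a) message-share: percent of impact-bearing messages carrying the
    category; (b) mention-share: percent of all category mentions.  The
    denominator is printed alongside every percentage.
    """
    from .reporting import qol_table
    counts = {c: int(predictions[c].sum()) for c in QOL_CATEGORIES}
    n_impact = int(predictions["has_impact"].sum())
    return qol_table(counts, n_impact)


# -- serialization ---------------------------------------------------------

def save_bundle(bundle: ImpactModelBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": _FORMAT_VERSION,
                "threshold": bundle.threshold, "seed": bundle.seed,
                "categories": list(bundle.categories)}
    (directory / "bundle.json").write_text(json.dumps(manifest))
    # serialize at booster level (robust across sklearn-wrapper versions)
    bundle.gate.get_booster().save_model(directory / "gate.ubj")
    for c, m in bundle.categories.items():
        m.get_booster().save_model(directory / f"category_{c}.ubj")


def load_bundle(directory: str | Path) -> ImpactModelBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "bundle.json").read_text())
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported bundle format "
                         f"{manifest.get('format_version')}")
    gate = _make_model(manifest["seed"])
    gate.load_model(directory / "gate.ubj")
    categories = {}
    for c in manifest["categories"]:
        m = _make_model(manifest["seed"])
        m.load_model(directory / f"category_{c}.ubj")
        categories[c] = m
    return ImpactModelBundle(gate=gate, categories=categories,
                             threshold=manifest["threshold"],
                             seed=manifest["seed"])
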