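"""Feature extraction, two-stage training/classification, gating, summary."""

import numpy as np
import pandas as pd
import pytest

from abxminer import impact_classifier as ic
from abxminer.corpus_filter import filter_corpus
from abxminer.lexicons import QOL_CATEGORIES
from abxminer.synthetic_data import GenerationConfig, generate_corpus

CAT_LIST = list(QOL_CATEGORIES)


def _labels(truth):
    return pd.DataFrame({
        c: truth["impact_categories"].astype(str).str.contains(c).to_numpy()
        for c in QOL_CATEGORIES})


@pytest.fixture(scope="module")
def trained(lex):
    """Bundle trained on ~2500 synthetic annotated posts + held-out split."""
    posts, truth = generate_corpus(GenerationConfig(n_users=1800, seed=77))
    kept, _ = filter_corpus(posts, lex)
    t = truth.set_index("post_id").loc[kept["id"]]
    y = t["has_impact"].to_numpy(bool)
    cats = _labels(t)
    n_train = int(len(kept) * 0.75)
    bundle = ic.train(list(kept["text"][:n_train]), y[:n_train],
                      cats.iloc[:n_train], lex, seed=0)
    return bundle, kept.iloc[n_train:].reset_index(drop=True), \
        y[n_train:], cats.iloc[n_train:].reset_index(drop=True)


class TestFeatures:
    def test_domain_hits_and_first_person(self, lex):
        v = ic.extract_features("je suis épuisée, douleurs partout", lex)
        names = dict(zip(ic.FEATURE_NAMES, v))
        assert names["qol_physical"] >= 2
        assert names["first_person"] > 0

    def test_zero_case(self, lex):
        v = ic.extract_features("bababa bebebe", lex)
        names = dict(zip(ic.FEATURE_NAMES, v))
        lexicon_feats = [k for k in names if k.startswith("qol_")
                         or k.startswith("sentiment")]
        assert all(names[k] == 0 for k in lexicon_feats)
        assert (v >= 0).all() and np.isfinite(v).all()

    def test_additivity_over_concatenation(self, lex):
        text = "je suis épuisée ! douleurs et angoisse, marre du travail"
        v1 = ic.extract_features(text, lex)
        v2 = ic.extract_features(text + " " + text, lex)
        np.testing.assert_allclose(v2, 2 * v1)


class TestTraining:
    def test_gate_accuracy_on_held_out(self, trained, lex):
        bundle, test_posts, y, _ = trained
        pred = ic.classify_corpus(test_posts, bundle, lex)
        assert (pred["has_impact"].to_numpy() == y).mean() >= 0.9

    def test_category_recall_on_held_out(self, trained, lex):
        bundle, test_posts, y, cats = trained
        pred = ic.classify_corpus(test_posts, bundle, lex)
        for c in QOL_CATEGORIES:
            true_pos = cats[c].to_numpy() & y
            if true_pos.sum() == 0:
                continue
            recall = (pred[c].to_numpy() & true_pos).sum() / true_pos.sum()
            assert recall >= 0.85, c

    def test_label_shuffle_scores_at_base_rate(self, lex):
        """Permutation control: with shuffled labels the gate cannot beat
        the majority-class rate beyond sampling noise."""
        posts, truth = generate_corpus(GenerationConfig(n_users=700, seed=55))
        kept, _ = filter_corpus(posts, lex)
        t = truth.set_index("post_id").loc[kept["id"]]
        y = t["has_impact"].to_numpy(bool)
        cats = _labels(t)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        n_train = len(kept) // 2
        bundle = ic.train(list(kept["text"][:n_train]), y_shuf[:n_train],
                          cats.iloc[:n_train], lex, seed=0)
        pred = ic.classify_corpus(kept.iloc[n_train:], bundle, lex)
        acc = (pred["has_impact"].to_numpy() == y_shuf[n_train:]).mean()
        base = max(y_shuf[n_train:].mean(), 1 - y_shuf[n_train:].mean())
        n = len(y_shuf) - n_train
        assert acc <= base + 3 * np.sqrt(base * (1 - base) / n)

    def test_training_reproducible(self, lex):
        posts, truth = generate_corpus(GenerationConfig(n_users=150, seed=2))
        kept, _ = filter_corpus(posts, lex)
        t = truth.set_index("post_id").loc[kept["id"]]
        args = (list(kept["text"]), t["has_impact"].to_numpy(bool),
                _labels(t), lex)
        p1 = ic.classify_corpus(kept, ic.train(*args, seed=9), lex)
        p2 = ic.classify_corpus(kept, ic.train(*args, seed=9), lex)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_target_named_error(self, lex):
        texts = ["douleurs partout"] * 10
        with pytest.raises(ValueError, match="gate"):
            ic.train(texts, np.ones(10, bool),
                     _labels(pd.DataFrame({"impact_categories":
                                           ["physical"] * 10})), lex)
        cats = pd.DataFrame({c: [i % 2 == 0 for i in range(10)]
                             if c == "physical" else [False] * 10
                             for c in QOL_CATEGORIES})
        y = np.array([True] * 9 + [False])
        with pytest.raises(ValueError, match="psychic"):
            ic.train(texts, y, cats, lex)


class TestGating:
    def test_gate_negative_has_no_categories(self, trained, lex):
        bundle, test_posts, _, _ = trained
        pred = ic.classify_corpus(test_posts, bundle, lex)
        negatives = pred[~pred["has_impact"]]
        assert not negatives[CAT_LIST].to_numpy().any()

    def test_single_post_prediction_gated(self, trained, lex):
        bundle, _, _, _ = trained
        p = ic.classify("bababa bebebe bibibi", bundle, lex)
        if not p.has_impact:
            assert p.category_probabilities == {} and p.categories == []

    def test_deterministic_rerun(self, trained, lex):
        bundle, test_posts, _, _ = trained
        text = test_posts["text"].iat[0]
        assert ic.classify(text, bundle, lex) == ic.classify(text, bundle, lex)


class TestSummary:
    def test_published_counts_reproduce_both_conventions(self):
        """physical 1866 of 2384 messages → 78%; of 4792 mentions → 39%."""
        from abxminer.reporting import qol_table
        counts = {"physical": 1866, "psychic": 1551, "activity": 745,
                  "relational": 602, "financial": 28}
        table = qol_table(counts, n_impact_messages=2384).set_index("category")
        assert table.loc["physical", "message_share_percent"] == 78
        assert table.loc["physical", "mention_share_percent"] == 39
        assert table.loc["psychic", "message_share_percent"] == 65
        assert table.loc["financial", "mention_share_percent"] == 1

    def test_single_message_single_category(self):
        from abxminer.reporting import qol_table
        t = qol_table({"physical": 1}, 1).set_index("category")
        assert t.loc["physical", "message_share_percent"] == 100
        assert t.loc["physical", "mention_share_percent"] == 100

    def test_empty_predictions_zeroed(self):
        pred = pd.DataFrame({"has_impact": []} | {c: [] for c in CAT_LIST})
        table = ic.impact_summary(pred)
        assert (table["count"] == 0).all()


def test_bundle_serialization_roundtrip(trained, lex, tmp_path):
    bundle, test_posts, _, _ = trained
    ic.save_bundle(bundle, tmp_path / "bundle")
    loaded = ic.load_bundle(tmp_path / "bundle")
    p1 = ic.classify_corpus(test_posts.head(20), bundle, lex)
    p2 = ic.classify_corpus(test_posts.head(20), loaded, lex)
    pd.testing.assert_frame_equal(p1, p2)
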