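"""Biterm topic model: preprocessing, sampler correctness, estimators,
document assignment and characteristic-token extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from abxminer import topic_model as tm
from abxminer.synthetic_data import (generate_topic_corpus, planted_blocks,
                                     pseudo_vocabulary)

from oracles import btm_exact_coassignment


def _corpus(docs, V):
    vocab = {f"w{i}": i for i in range(V)}
    return tm.TokenizedCorpus([np.asarray(d, np.int32) for d in docs],
                              vocab, list(vocab))


class TestPreprocess:
    def test_rules_applied(self):
        corpus = tm.preprocess(["Les antibiotiques ne marchent PAS!"],
                               stopwords=["les", "ne", "pas"])
        assert corpus.id_to_token == ["antibiotiques", "marchent"]

    def test_deterministic_ids(self):
        texts = ["alpha beta gamma", "beta delta"]
        c1 = tm.preprocess(texts, [])
        c2 = tm.preprocess(texts, [])
        assert c1.vocabulary == c2.vocabulary
        assert [d.tolist() for d in c1.documents] == \
            [d.tolist() for d in c2.documents]

    def test_short_tokens_and_accents(self):
        corpus = tm.preprocess(["Où ça me Gêne dépistage"], stopwords=[])
        assert corpus.id_to_token == ["gene", "depistage"]

    def test_all_stopword_document_flagged(self):
        corpus = tm.preprocess(["le la les", "alpha beta"],
                               stopwords=["le", "la", "les"])
        assert corpus.short_documents == [0]
        assert len(tm.extract_biterms(corpus.documents[0])) == 0

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            tm.preprocess(["le la"], stopwords=["le", "la"])


class TestBiterms:
    def test_three_tokens(self):
        assert tm.extract_biterms(np.array([0, 1, 2])) == \
            [(0, 1), (0, 2), (1, 2)]

    def test_repeated_token_self_pair(self):
        assert tm.extract_biterms(np.array([3, 3])) == [(3, 3)]

    def test_ordering_convention(self):
        assert tm.extract_biterms(np.array([5, 2])) == [(2, 5)]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 9), min_size=0, max_size=12))
    def test_count_identity(self, doc):
        n = len(doc)
        assert len(tm.extract_biterms(np.asarray(doc))) == n * (n - 1) // 2


class TestFit:
    def test_single_topic_closed_form(self):
        corpus = _corpus([[0, 1, 2], [1, 2, 3, 3]], V=4)
        state = tm.fit(corpus, K=1, n_iterations=20, burn_in=10, seed=0)
        assert (state.z == 0).all()
        w1, w2 = tm.corpus_biterms(corpus)
        counts = np.bincount(np.concatenate([w1, w2]), minlength=4)
        expected = (counts + state.beta) / (2 * len(w1) + 4 * state.beta)
        np.testing.assert_allclose(tm.topic_word_distribution(state)[:, 0],
                                   expected)
        np.testing.assert_allclose(tm.corpus_topic_distribution(state), [1.0])

    def test_count_invariants_every_sweep(self):
        corpus = _corpus([[0, 1, 2], [2, 3], [0, 3, 4]], V=5)
        w1, w2 = tm.corpus_biterms(corpus)
        rng = np.random.default_rng(0)
        state = tm._init_state(w1, w2, K=3, V=5, alpha=1.0, beta=0.1,
                               rng=rng, seed=0)
        for _ in range(25):
            tm.gibbs_sweeps(state, rng, 1)
            state.check_invariants()

    def test_seed_reproducibility(self):
        corpus = _corpus([[0, 1], [1, 2], [2, 3]], V=4)
        s1 = tm.fit(corpus, K=2, n_iterations=30, burn_in=10, seed=7)
        s2 = tm.fit(corpus, K=2, n_iterations=30, burn_in=10, seed=7)
        np.testing.assert_array_equal(s1.z, s2.z)
        np.testing.assert_allclose(s1.phi_mean, s2.phi_mean)

    def test_degenerate_k_warns_but_runs(self):
        corpus = _corpus([[0, 1]], V=2)
        with pytest.warns(UserWarning, match="degenerate"):
            tm.fit(corpus, K=5, n_iterations=10, burn_in=5, seed=0)

    def test_gibbs_matches_exact_posterior_small(self):
        """Co-assignment frequencies vs brute-force enumeration (4 biterms,
        K=3, includes a repeated-token self-pair)."""
        corpus = _corpus([[0, 0, 1], [2, 3]], V=4)
        w1, w2 = tm.corpus_biterms(corpus)
        K, alpha, beta = 3, 0.7, 0.3
        exact = btm_exact_coassignment(w1, w2, K, 4, alpha, beta)
        rng = np.random.default_rng(5)
        state = tm._init_state(w1, w2, K, 4, alpha, beta, rng, 5)
        tm.gibbs_sweeps(state, rng, 500)
        B = len(w1)
        emp = np.zeros((B, B))
        n_samples = 10000
        for _ in range(n_samples):
            tm.gibbs_sweeps(state, rng, 1)
            emp += state.z[:, None] == state.z[None, :]
        emp /= n_samples
        assert np.abs(emp - exact).max() < 0.03

    def test_large_beta_drives_phi_uniform(self):
        corpus = _corpus([[0, 1], [2, 3], [0, 3]], V=4)
        state = tm.fit(corpus, K=2, beta=1e6, n_iterations=30, burn_in=10,
                       seed=1)
        np.testing.assert_allclose(tm.topic_word_distribution(state), 0.25,
                                   atol=1e-4)

    def test_unfitted_state_estimators_raise(self):
        corpus = _corpus([[0, 1]], V=2)
        w1, w2 = tm.corpus_biterms(corpus)
        rng = np.random.default_rng(0)
        state = tm._init_state(w1, w2, 1, 2, 1.0, 0.1, rng, 0)
        with pytest.raises(tm.NotFittedError):
            tm.topic_word_distribution(state)


class TestAssignment:
    @pytest.fixture(scope="class")
    def fitted(self):
        texts, labels, _ = generate_topic_corpus(300, K=3, V=60, doc_len=8,
                                                 seed=3)
        corpus = tm.preprocess(texts, [])
        state = tm.fit(corpus, K=3, n_iterations=200, burn_in=100, seed=3)
        return corpus, state, labels

    def test_k1_always_topic_zero(self):
        corpus = _corpus([[0, 1, 2], [1, 2]], V=3)
        state = tm.fit(corpus, K=1, n_iterations=10, burn_in=5, seed=0)
        assert tm.assign_corpus(corpus, state).tolist() == [0, 0]

    def test_single_biterm_collapses_to_formula(self, fitted):
        _, state, _ = fitted
        doc = np.array([0, 1], np.int32)
        phi = tm.topic_word_distribution(state)
        theta = tm.corpus_topic_distribution(state)
        expected = int(np.argmax(theta * phi[0] * phi[1]))
        assert tm.assign_document(doc, state) == expected

    def test_empty_document_unassigned(self, fitted):
        _, state, _ = fitted
        assert tm.assign_document(np.array([], np.int32), state) == \
            tm.UNASSIGNED

    def test_single_token_document_assigned(self, fitted):
        _, state, _ = fitted
        assert tm.assign_document(np.array([0], np.int32), state) >= 0

    def test_planted_assignment_accuracy(self, fitted):
        corpus, state, labels = fitted
        pred = tm.assign_corpus(corpus, state)
        conf = np.zeros((3, 3))
        for a, l in zip(pred, labels):
            conf[a, l] += 1
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / len(labels) >= 0.85


class TestCharacteristicTokens:
    def test_weight_formula(self):
        phi = np.array([[0.3, 0.01, 0.02],
                        [0.7, 0.99, 0.98]])  # V=2, K=3
        summary = tm.characteristic_tokens(phi, k=0, n=2)
        weights = dict(summary.tokens)
        assert weights["0"] == pytest.approx(0.3 / 0.03)

    def test_uniform_token_never_characteristic(self):
        K = 4
        phi = np.full((1, K), 0.25)
        s = tm.characteristic_tokens(phi, k=1, n=1)
        assert s.tokens[0][1] == pytest.approx(1 / (K - 1))

    def test_k1_falls_back_to_raw_phi(self):
        phi = np.array([[0.5], [0.3], [0.2]])
        s = tm.characteristic_tokens(phi, k=0, n=3)
        assert [t for t, _ in s.tokens] == ["0", "1", "2"]

    def test_exactly_min_15_v_tokens_descending(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(40), size=3).T  # V=40, K=3
        s = tm.characteristic_tokens(phi, k=2)
        assert len(s.tokens) == 15
        ws = [w for _, w in s.tokens]
        assert all(a >= b for a, b in zip(ws, ws[1:]))

    def test_planted_topics_yield_block_tokens(self):
        texts, _, _ = generate_topic_corpus(400, K=3, V=60, doc_len=8, seed=9)
        corpus = tm.preprocess(texts, [])
        state = tm.fit(corpus, K=3, n_iterations=200, burn_in=100, seed=9)
        words = pseudo_vocabulary(60)
        blocks = [set(words[i] for i in b) for b in planted_blocks(3, 60)]
        summaries = tm.summarize_topics(state, corpus.id_to_token)
        best = 0
        for s in summaries:
            toks = {t for t, _ in s.tokens}
            best += max(len(toks & b) for b in blocks)
        assert best / (3 * 15) >= 13 / 15


def test_document_order_exchangeability():
    """Permuting document order leaves recovered topics aligned (up to
    label permutation) on a well-separated corpus."""
    texts, _, _ = generate_topic_corpus(200, K=2, V=40, doc_len=8, seed=21)
    c1 = tm.preprocess(texts, [])
    c2 = tm.preprocess(texts[::-1], [])
    s1 = tm.fit(c1, K=2, n_iterations=150, burn_in=75, seed=0)
    s2 = tm.fit(c2, K=2, n_iterations=150, burn_in=75, seed=1)
    top = lambda c, s, k: {c.id_to_token[i] for i in
                           np.argsort(-tm.topic_word_distribution(s)[:, k])[:10]}
    sets1 = [top(c1, s1, k) for k in range(2)]
    sets2 = [top(c2, s2, k) for k in range(2)]
    overlap = max(len(sets1[0] & sets2[0]) + len(sets1[1] & sets2[1]),
                  len(sets1[0] & sets2[1]) + len(sets1[1] & sets2[0]))
    assert overlap >= 18


def test_state_serialization_roundtrip(tmp_path):
    corpus = _corpus([[0, 1, 2], [2, 3]], V=4)
    state = tm.fit(corpus, K=2, n_iterations=20, burn_in=10, seed=0)
    path = tmp_path / "state.json"
    tm.save_state(state, path)
    loaded = tm.load_state(path)
    np.testing.assert_array_equal(loaded.z, state.z)
    np.testing.assert_allclose(loaded.phi_mean, state.phi_mean)
    assert loaded.K == state.K and loaded.fitted
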