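"""Biterm topic model (BTM) for short forum messages.

Short posts give classical per-document topic models too little
co-occurrence signal, so the BTM instead models the corpus-wide set of
*biterms* — unordered pairs of tokens co-occurring within one message — as
a single mixture over K topics: a topic proportion vector θ ~ Dirichlet(α)
and per-topic word distributions φ_k ~ Dirichlet(β); each biterm picks a
topic z_b ~ θ and draws both words from φ_{z_b}.

Inference is collapsed Gibbs sampling over the biterm topic assignments,
with parameter estimates

    φ_w|k = (n_wk + β) / (2 n_k + V β),     θ_k = (n_k + α) / (B + K α)

averaged over post-burn-in samples.  Documents receive a single topic via
P(k|d) = Σ_b P(k|b) P(b|d), and each topic is summarized by its 15
*characteristic tokens*: tokens ranked by their in-topic probability
weighted by the inverse of their summed probability in the other topics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._gibbs import run_sweeps
from .textnorm import tokenize

UNASSIGNED = -1
N_CHARACTERISTIC = 15


class NotFittedError(RuntimeError):
    pass


# -- preprocessing ---------------------------------------------------------

@dataclass
class TokenizedCorpus:
    documents: list[np.ndarray]           # int32 token ids per document
    vocabulary: dict[str, int]            # token -> id
    id_to_token: list[str]

    @property
    def V(self) -> int:
        return len(self.id_to_token)

    @property
    def short_documents(self) -> list[int]:
        """Indices of documents with < 2 tokens (no biterm extractable)."""
        return [i for i, d in enumerate(self.documents) if len(d) < 2]


def preprocess(texts: list[str], stopwords: list[str],
               min_length: int = 3) -> TokenizedCorpus:
    """Lowercase, accent-fold, split on non-letters, drop stopwords and
    tokens shorter than `min_length`; vocabulary ordered by first occurrence."""
    stop = frozenset(stopwords)
    vocab: dict[str, int] = {}
    docs = []
    for text in texts:
        ids = []
        for tok in tokenize(text):
            if tok in stop or len(tok) < min_length:
                continue
            if tok not in vocab:
                vocab[tok] = len(vocab)
            ids.append(vocab[tok])
        docs.append(np.asarray(ids, dtype=np.int32))
    if not vocab:
        raise ValueError("empty vocabulary after stopword/length filtering")
    id_to_token = [None] * len(vocab)
    for tok, i in vocab.items():
        id_to_token[i] = tok
    return TokenizedCorpus(docs, vocab, id_to_token)


def extract_biterms(doc: np.ndarray) -> list[tuple[int, int]]:
    """All C(n, 2) unordered token pairs over distinct positions.

    Pairs are stored (min id, max id); a repeated token yields self-pairs.
    Documents with fewer than 2 tokens yield no biterms.
    """
    n = len(doc)
    out = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            a, b = int(doc[i]), int(doc[j])
            out.append((a, b) if a <= b else (b, a))
    return out


def corpus_biterms(corpus: TokenizedCorpus) -> tuple[np.ndarray, np.ndarray]:
    w1, w2 = [], []
    for doc in corpus.documents:
        for a, b in extract_biterms(doc):
            w1.append(a)
            w2.append(b)
    return (np.asarray(w1, dtype=np.int32), np.asarray(w2, dtype=np.int32))


# -- model state -----------------------------------------------------------

@dataclass
class TopicModelState:
    """Sufficient statistics of the collapsed sampler plus posterior means."""

    K: int
    V: int
    alpha: float
    beta: float
    w1: np.ndarray = field(repr=False)            # int32[B]
    w2: np.ndarray = field(repr=False)            # int32[B]
    z: np.ndarray = field(repr=False)             # int32[B]
    n_k: np.ndarray = field(repr=False)           # float64[K]
    n_wk: np.ndarray = field(repr=False)          # float64[V, K]
    seed: int = 0
    phi_mean: np.ndarray | None = field(default=None, repr=False)
    theta_mean: np.ndarray | None = field(default=None, repr=False)
    n_samples: int = 0
    fitted: bool = False

    @property
    def B(self) -> int:
        return len(self.z)

    def check_invariants(self) -> None:
        assert self.n_k.sum() == self.B, "sum n_k != B"
        np.testing.assert_array_equal(self.n_wk.sum(axis=0), 2 * self.n_k)
        assert (self.n_k >= 0).all() and (self.n_wk >= 0).all()

    def phi_from_counts(self) -> np.ndarray:
        """φ (V × K) from the current counts."""
        return (self.n_wk + self.beta) / (2 * self.n_k + self.V * self.beta)

    def theta_from_counts(self) -> np.ndarray:
        return (self.n_k + self.alpha) / (self.B + self.K * self.alpha)


def _init_state(w1: np.ndarray, w2: np.ndarray, K: int, V: int,
                alpha: float, beta: float, rng: np.random.Generator,
                seed: int) -> TopicModelState:
    B = len(w1)
    z = rng.integers(0, K, size=B).astype(np.int32)
    n_k = np.zeros(K)
    n_wk = np.zeros((V, K))
    for b in range(B):
        n_k[z[b]] += 1
        n_wk[w1[b], z[b]] += 1
        n_wk[w2[b], z[b]] += 1
    return TopicModelState(K=K, V=V, alpha=alpha, beta=beta, w1=w1, w2=w2,
                           z=z, n_k=n_k, n_wk=n_wk, seed=seed)


def gibbs_sweeps(state: TopicModelState, rng: np.random.Generator,
                 n_sweeps: int = 1) -> None:
    """Run full Gibbs sweeps in place (uniform variates drawn from `rng`)."""
    rand = rng.random((n_sweeps, state.B))
    run_sweeps(state.w1, state.w2, state.z, state.n_k, state.n_wk,
               state.alpha, state.beta, state.V, rand)


def fit(corpus: TokenizedCorpus, K: int, alpha: float | None = None,
        beta: float = 0.01, n_iterations: int = 1000, burn_in: int = 500,
        thin: int = 10, seed: int = 0) -> TopicModelState:
    """Collapsed Gibbs sampling; φ and θ averaged over post-burn-in samples.

    Defaults α = 50/K and β = 0.01 follow common BTM practice.  Identical
    seed reproduces the final state exactly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if burn_in >= n_iterations:
        raise ValueError("burn_in must be below n_iterations")
    w1, w2 = corpus_biterms(corpus)
    if len(w1) == 0:
        raise ValueError("corpus contains no biterm (all documents too short)")
    if K > len(w1):
        warnings.warn(f"K={K} exceeds the number of biterms B={len(w1)}; "
                      "the model is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    state = _init_state(w1, w2, K, corpus.V, alpha, beta, rng, seed)
    phi_sum = np.zeros((corpus.V, K))
    theta_sum = np.zeros(K)
    n_samples = 0
    for sweep in range(1, n_iterations + 1):
        gibbs_sweeps(state, rng, 1)
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            phi_sum += state.phi_from_counts()
            theta_sum += state.theta_from_counts()
            n_samples += 1
    if n_samples == 0:
        # run too short for the thinning schedule: use the final state
        phi_sum = state.phi_from_counts()
        theta_sum = state.theta_from_counts()
        n_samples = 1
    state.phi_mean = phi_sum / n_samples
    state.theta_mean = theta_sum / n_samples
    state.n_samples = n_samples
    state.fitted = True
    return state


def topic_word_distribution(state: TopicModelState) -> np.ndarray:
    """φ as a V × K matrix; each column sums to 1."""
    if not state.fitted:
        raise NotFittedError("state is not fitted; run fit() first")
    return state.phi_mean


def corpus_topic_distribution(state: TopicModelState) -> np.ndarray:
    """θ as a length-K probability vector."""
    if not state.fitted:
        raise NotFittedError("state is not fitted; run fit() first")
    return state.theta_mean


# -- document assignment ---------------------------------------------------

def assign_document(doc: np.ndarray, state: TopicModelState) -> int:
    """Single topic for one tokenized document (argmax of P(k|d)).

    P(k|d) = Σ_b P(k|b) with P(k|b) ∝ θ_k φ_w1|k φ_w2|k and uniform P(b|d);
    documents without a biterm fall back to the single-token mixture
    P(k|w) ∝ θ_k φ_w|k; empty documents return the UNASSIGNED sentinel.
    Ties break to the lowest topic index.
    """
    if len(doc) == 0:
        return UNASSIGNED
    phi = topic_word_distribution(state)
    theta = corpus_topic_distribution(state)
    score = np.zeros(state.K)
    biterms = extract_biterms(doc)
    if biterms:
        for a, b in biterms:
            p = theta * phi[a] * phi[b]
            score += p / p.sum()
    else:
        for w in doc:
            p = theta * phi[int(w)]
            score += p / p.sum()
    return int(np.argmax(score))


def assign_corpus(corpus: TokenizedCorpus,
                  state: TopicModelState) -> np.ndarray:
    return np.array([assign_document(d, state) for d in corpus.documents])


# -- characteristic tokens -------------------------------------------------

@dataclass
class TopicSummary:
    topic: int
    tokens: list[tuple[str, float]]       # (token, weight), weight descending
    label: str | None = None              # manual label slot


def characteristic_tokens(phi: np.ndarray, k: int, n: int = N_CHARACTERISTIC,
                          id_to_token: list[str] | None = None) -> TopicSummary:
    """Top-n tokens of topic k by cross-topic weighted probability.

    weight(t, k) = φ_t|k / Σ_{k'≠k} φ_t|k' — the in-topic probability
    weighted by the inverse of the token's probability in the other topics
    (for K = 1 the raw φ ranking is used).  Ties break by raw φ, then by
    token id.
    """
    V, K = phi.shape
    col = phi[:, k]
    if K == 1:
        weight = col.copy()
    else:
        other = phi.sum(axis=1) - col
        weight = col / other
    n = min(n, V)
    order = sorted(range(V), key=lambda t: (-weight[t], -col[t], t))[:n]
    names = id_to_token if id_to_token is not None else [str(t) for t in range(V)]
    return TopicSummary(topic=k, tokens=[(names[t], float(weight[t]))
                                         for t in order])


def summarize_topics(state: TopicModelState,
                     id_to_token: list[str] | None = None,
                     n: int = N_CHARACTERISTIC) -> list[TopicSummary]:
    phi = topic_word_distribution(state)
    return [characteristic_tokens(phi, k, n, id_to_token)
            for k in range(state.K)]


# -- model selection aid ---------------------------------------------------

def umass_coherence(corpus: TokenizedCorpus, top_tokens: list[list[int]]) -> float:
    """Mean UMass coherence of the given per-topic top-token id lists."""
    doc_sets = [set(map(int, d)) for d in corpus.documents]
    df: dict[int, int] = {}
    for toks in top_tokens:
        for t in toks:
            if t not in df:
                df[t] = sum(t in s for s in doc_sets)
    score = 0.0
    n_pairs = 0
    for toks in top_tokens:
        for i in range(1, len(toks)):
            for j in range(i):
                co = sum(toks[i] in s and toks[j] in s for s in doc_sets)
                score += np.log((co + 1) / max(df[toks[j]], 1))
                n_pairs += 1
    return score / max(n_pairs, 1)


def coherence_sweep(corpus: TokenizedCorpus, k_values: list[int],
                    n_top: int = 10, seed: int = 0,
                    **fit_kwargs) -> dict[int, float]:
    """UMass coherence for a range of K, to aid choosing the topic count."""
    out = {}
    for K in k_values:
        state = fit(corpus, K=K, seed=seed, **fit_kwargs)
        phi = topic_word_distribution(state)
        tops = [list(np.argsort(-phi[:, k])[:n_top]) for k in range(K)]
        out[K] = umass_coherence(corpus, tops)
    return out


# -- serialization ---------------------------------------------------------

_FORMAT_VERSION = 1


def save_state(state: TopicModelState, path: str | Path) -> None:
    """Versioned JSON bundle of the fitted state."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "K": state.K, "V": state.V, "alpha": state.alpha, "beta": state.beta,
        "seed": state.seed, "n_samples": state.n_samples,
        "fitted": state.fitted,
        "w1": state.w1.tolist(), "w2": state.w2.tolist(),
        "z": state.z.tolist(), "n_k": state.n_k.tolist(),
        "n_wk": state.n_wk.tolist(),
        "phi_mean": None if state.phi_mean is None else state.phi_mean.tolist(),
        "theta_mean": (None if state.theta_mean is None
                       else state.theta_mean.tolist()),
    }
    Path(path).write_text(json.dumps(payload))


def load_state(path: str | Path) -> TopicModelState:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported state format: {d.get('format_version')}")
    state = TopicModelState(
        K=d["K"], V=d["V"], alpha=d["alpha"], beta=d["beta"],
        w1=np.asarray(d["w1"], np.int32), w2=np.asarray(d["w2"], np.int32),
        z=np.asarray(d["z"], np.int32), n_k=np.asarray(d["n_k"], float),
        n_wk=np.asarray(d["n_wk"], float), seed=d["seed"],
        n_samples=d["n_samples"], fitted=d["fitted"])
    if d["phi_mean"] is not None:
        state.phi_mean = np.asarray(d["phi_mean"], float)
    if d["theta_mean"] is not None:
        state.theta_mean = np.asarray(d["theta_mean"], float)
    return state
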