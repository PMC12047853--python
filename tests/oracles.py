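"""Independent brute-force oracles used by the test suite.

Kept free of any abxminer inference code: the BTM posterior is enumerated
directly from the collapsed joint of the generative model (Dirichlet-
multinomial integrals), so it can arbitrate the Gibbs sampler.
"""

from itertools import product
from math import lgamma

import numpy as np


def btm_log_joint(z, w1, w2, K, V, alpha, beta):
    """Collapsed log P(z) of the biterm topic model, up to a constant."""
    n_k = np.zeros(K)
    n_wk = np.zeros((V, K))
    for b, k in enumerate(z):
        n_k[k] += 1
        n_wk[w1[b], k] += 1
        n_wk[w2[b], k] += 1
    lp = 0.0
    for k in range(K):
        lp += lgamma(n_k[k] + alpha) - lgamma(alpha)
        lp += lgamma(V * beta) - lgamma(2 * n_k[k] + V * beta)
        for w in range(V):
            lp += lgamma(n_wk[w, k] + beta) - lgamma(beta)
    return lp


def btm_exact_posterior(w1, w2, K, V, alpha, beta):
    """Exact posterior over all K^B assignments; returns (assignments, probs)."""
    B = len(w1)
    assigns = list(product(range(K), repeat=B))
    logs = np.array([btm_log_joint(z, w1, w2, K, V, alpha, beta)
                     for z in assigns])
    p = np.exp(logs - logs.max())
    return assigns, p / p.sum()


def btm_exact_marginals(w1, w2, K, V, alpha, beta):
    """Per-biterm topic marginals P(z_b = k)."""
    assigns, p = btm_exact_posterior(w1, w2, K, V, alpha, beta)
    B = len(w1)
    marg = np.zeros((B, K))
    for pi, z in zip(p, assigns):
        for b, k in enumerate(z):
            marg[b, k] += pi
    return marg


def btm_exact_coassignment(w1, w2, K, V, alpha, beta):
    """Pairwise co-assignment probabilities P(z_i = z_j).

    Unlike the per-biterm marginals (uniform by topic-label symmetry),
    these are label-invariant and discriminate between samplers.
    """
    assigns, p = btm_exact_posterior(w1, w2, K, V, alpha, beta)
    B = len(w1)
    co = np.zeros((B, B))
    for pi, z in zip(p, assigns):
        za = np.asarray(z)
        co += pi * (za[:, None] == za[None, :])
    return co
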