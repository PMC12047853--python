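"""Numba kernel for the collapsed Gibbs sweep of the biterm topic model.

The uniform variates are generated *outside* by a seeded numpy Generator and
passed in, so runs are reproducible and the same kernel serves both batch
fitting and stepwise sampling.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_sweeps(w1, w2, z, n_k, n_wk, alpha, beta, V, rand):
    """In-place Gibbs sweeps over all biterms.

    w1, w2 : int32[B]   word ids of each biterm (w1 <= w2)
    z      : int32[B]   current topic assignment, updated in place
    n_k    : float64[K] biterms per topic, updated in place
    n_wk   : float64[V, K] word-in-topic counts, updated in place
    rand   : float64[S, B] uniform variates, one per (sweep, biterm)

    The conditional for biterm b = (u, v):
        P(z_b = k | z_-b) ∝ (n_-b,k + alpha)
            * (n_-b,u|k + beta) * (n_-b,v|k + beta + [u == v])
            / ((2 n_-b,k + V beta) * (2 n_-b,k + 1 + V beta))
    (the extra [u == v] term is the exact collapsed conditional when the
    biterm repeats a token; for distinct tokens it is the standard form).
    """
    S, B = rand.shape
    K = n_k.shape[0]
    probs = np.empty(K)
    for s in range(S):
        for b in range(B):
            u = w1[b]
            v = w2[b]
            old = z[b]
            n_k[old] -= 1.0
            n_wk[u, old] -= 1.0
            n_wk[v, old] -= 1.0
            same = 1.0 if u == v else 0.0
            total = 0.0
            for k in range(K):
                nk = n_k[k]
                p = (nk + alpha) \
                    * (n_wk[u, k] + beta) * (n_wk[v, k] + beta + same) \
                    / ((2.0 * nk + V * beta) * (2.0 * nk + 1.0 + V * beta))
                probs[k] = p
                total += p
            r = rand[s, b] * total
            acc = 0.0
            new = K - 1
            for k in range(K):
                acc += probs[k]
                if r < acc:
                    new = k
                    break
            z[b] = new
            n_k[new] += 1.0
            n_wk[u, new] += 1.0
            n_wk[v, new] += 1.0
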