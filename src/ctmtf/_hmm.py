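"""Numba kernels for the copy-state hidden Markov chain.

The transition matrix is exchangeable: probability ``s`` of staying in the
current copy state and ``(1 - s) / (K - 1)`` of moving to any other state,
which lets the forward/backward recursions use the rank-one identity
``A @ v = (s - o) * v + o * sum(v)`` instead of a full matrix product.
Emissions are Gaussian with state-specific means and a shared variance.
Scaling uses a per-bin max-shift of the log emission densities, so the
recursions stay finite even when the shared variance collapses on
noise-free input.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(r, mu, sigma2, self_t):
    """Posterior state probabilities and data log-likelihood.

    Parameters: observations ``r`` (T,), state means ``mu`` (K,), shared
    variance ``sigma2``, self-transition probability ``self_t``.
    Returns ``(loglik, gamma)`` with ``gamma`` of shape (T, K).
    """
    T = r.size
    K = mu.size
    o = (1.0 - self_t) / (K - 1)
    d = self_t - o

    logB = np.empty((T, K))
    shift = np.empty(T)
    c0 = -0.5 * np.log(2.0 * np.pi * sigma2)
    inv2s = 0.5 / sigma2
    for t in range(T):
        m = -1e308
        for k in range(K):
            v = c0 - (r[t] - mu[k]) ** 2 * inv2s
            logB[t, k] = v
            if v > m:
                m = v
        shift[t] = m

    B = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - shift[t])

    alpha = np.empty((T, K))
    scale = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = B[0, k] / K
        s += alpha[0, k]
    scale[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            # sum over previous alpha is 1 after normalisation
            a = d * alpha[t - 1, k] + o
            alpha[t, k] = a * B[t, k]
            s += alpha[t, k]
        scale[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        tot = 0.0
        for k in range(K):
            tot += B[t + 1, k] * beta[t + 1, k]
        for k in range(K):
            v = d * (B[t + 1, k] * beta[t + 1, k]) + o * tot
            beta[t, k] = v / scale[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            g = alpha[t, k] * beta[t, k]
            gamma[t, k] = g
            s += g
        for k in range(K):
            gamma[t, k] /= s

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t]) + shift[t]
    return loglik, gamma


@njit(cache=True)
def viterbi(r, mu, sigma2, self_t):
    """Most probable copy-state path (uniform initial distribution)."""
    T = r.size
    K = mu.size
    o = (1.0 - self_t) / (K - 1)
    log_s = np.log(self_t)
    log_o = np.log(o)
    c0 = -0.5 * np.log(2.0 * np.pi * sigma2)
    inv2s = 0.5 / sigma2

    delta = np.empty(K)
    for k in range(K):
        delta[k] = c0 - (r[0] - mu[k]) ** 2 * inv2s - np.log(K)
    back = np.empty((T, K), dtype=np.int64)
    newd = np.empty(K)
    for t in range(1, T):
        best = 0
        for k in range(1, K):
            if delta[k] > delta[best]:
                best = k
        for k in range(K):
            stay = delta[k] + log_s
            move = delta[best] + log_o
            if k == best:
                # best predecessor other than k itself
                second = -1
                for j in range(K):
                    if j != k and (second < 0 or delta[j] > delta[second]):
                        second = j
                move = delta[second] + log_o
                prev = second
            else:
                prev = best
            if stay >= move:
                back[t, k] = k
                v = stay
            else:
                back[t, k] = prev
                v = move
            newd[k] = v + c0 - (r[t] - mu[k]) ** 2 * inv2s
        for k in range(K):
            delta[k] = newd[k]

    path = np.empty(T, dtype=np.int64)
    best = 0
    for k in range(1, K):
        if delta[k] > delta[best]:
            best = k
    path[T - 1] = best
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
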