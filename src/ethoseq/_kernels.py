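"""Numba inner loops: Markov-chain sampling, scaled forward-backward, Viterbi.

All randomness enters as pre-drawn uniform/normal arrays from a numpy
Generator, so results are bit-reproducible for a given seed regardless of
numba version.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sample_chain(cum_trans, cum_init, uniforms):
    """Sample a Markov chain path from row-wise cumulative probabilities.

    cum_trans: (K, K) cumulative rows; cum_init: (K,); uniforms: (T,).
    """
    T = uniforms.shape[0]
    K = cum_init.shape[0]
    states = np.empty(T, dtype=np.int64)
    u = uniforms[0]
    s = K - 1
    for k in range(K):
        if u < cum_init[k]:
            s = k
            break
    states[0] = s
    for t in range(1, T):
        u = uniforms[t]
        row = cum_trans[s]
        s = K - 1
        for k in range(K):
            if u < row[k]:
                s = k
                break
        states[t] = s
    return states


@njit(cache=True)
def ar_emit(states, ar_coefs, intercepts, chols, warmup, noise):
    """Emit an AR(L) observation sequence given a state path.

    states: (T,); ar_coefs: (K, L, P, P); chols: (K, P, P) lower Cholesky of
    innovation covariances; warmup: (L, P) initial frames; noise: (T, P) std
    normal draws.  Frames 0..L-1 are taken from ``warmup`` verbatim.
    """
    T = states.shape[0]
    K, L, P, _ = ar_coefs.shape
    X = np.empty((T, P))
    for l in range(L):
        X[l] = warmup[l]
    for t in range(L, T):
        k = states[t]
        x = intercepts[k].copy()
        for l in range(L):
            x += ar_coefs[k, l] @ X[t - 1 - l]
        x += chols[k] @ noise[t]
        X[t] = x
    return X


@njit(cache=True)
def forward_backward(logB, trans, init):
    """Scaled forward-backward on one contiguous block.

    logB: (M, K) per-frame emission log-likelihoods.
    Returns (gamma (M, K), xi_sum (K, K), start_gamma (K,), loglik).
    """
    M, K = logB.shape
    alpha = np.empty((M, K))
    beta = np.empty((M, K))
    c = np.empty(M)
    shift = np.empty(M)
    B = np.empty((M, K))
    for t in range(M):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        shift[t] = m
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - m)

    # forward
    s = 0.0
    for k in range(K):
        alpha[0, k] = init[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, M):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * trans[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    # backward
    for k in range(K):
        beta[M - 1, k] = 1.0
    for t in range(M - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += trans[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]

    gamma = np.empty((M, K))
    for t in range(M):
        s = 0.0
        for k in range(K):
            g = alpha[t, k] * beta[t, k]
            gamma[t, k] = g
            s += g
        for k in range(K):
            gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(1, M):
        for i in range(K):
            ai = alpha[t - 1, i]
            for j in range(K):
                xi_sum[i, j] += ai * trans[i, j] * B[t, j] * beta[t, j] / c[t]

    ll = 0.0
    for t in range(M):
        ll += np.log(c[t]) + shift[t]
    return gamma, xi_sum, gamma[0].copy(), ll


@njit(cache=True)
def viterbi(logB, log_trans, log_init):
    """Max-a-posteriori state path for one contiguous block.

    Ties are broken toward the lowest state index (first argmax).
    Returns (path (M,), path log-likelihood).
    """
    M, K = logB.shape
    delta = np.empty((M, K))
    psi = np.empty((M, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_init[k] + logB[0, k]
        psi[0, k] = 0
    for t in range(1, M):
        for j in range(K):
            best = delta[t - 1, 0] + log_trans[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            psi[t, j] = arg
    best = delta[M - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[M - 1, k] > best:
            best = delta[M - 1, k]
            arg = k
    path = np.empty(M, dtype=np.int64)
    path[M - 1] = arg
    for t in range(M - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
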