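"""Numerical kernels for the Gaussian-emission HMM (scaled forward-backward
and log-space Viterbi).  Compiled with numba; inputs are plain float arrays.

The forward-backward kernel works in probability space with per-step
normalization constants c_t; emission probabilities are expected pre-scaled
per time step (exp(logB - rowmax)), the caller adds the row maxima back into
the log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(B, A, pi):
    """Scaled forward-backward for one sequence.

    B: (N, K) emission probabilities (any positive per-row scaling),
    A: (K, K) transition matrix, pi: (K,) initial distribution.
    Returns (gamma, xi_sum, logc, ok): posteriors, summed two-slice
    posteriors, sum of log normalizers, and a success flag.
    """
    N, K = B.shape
    alpha = np.empty((N, K))
    c = np.empty(N)
    s = 0.0
    for j in range(K):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    if s <= 0.0 or not np.isfinite(s):
        return alpha, np.zeros((K, K)), 0.0, False
    c[0] = s
    for j in range(K):
        alpha[0, j] /= s
    for t in range(1, N):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * A[i, j]
            acc *= B[t, j]
            alpha[t, j] = acc
            s += acc
        if s <= 0.0 or not np.isfinite(s):
            return alpha, np.zeros((K, K)), 0.0, False
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((N, K))
    gamma = np.empty((N, K))
    xi = np.zeros((K, K))
    for j in range(K):
        beta[N - 1, j] = 1.0
        gamma[N - 1, j] = alpha[N - 1, j]
    for t in range(N - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
            gamma[t, i] = alpha[t, i] * beta[t, i]
    for t in range(1, N):
        for i in range(K):
            ai = alpha[t - 1, i]
            if ai == 0.0:
                continue
            for j in range(K):
                xi[i, j] += ai * A[i, j] * B[t, j] * beta[t, j] / c[t]

    logc = 0.0
    for t in range(N):
        logc += np.log(c[t])
    return gamma, xi, logc, True


@njit(cache=True)
def viterbi(logB, logA, logpi):
    """Most probable state path in log space; ties break toward the lower
    state index (strict-improvement scan in index order)."""
    N, K = logB.shape
    delta = np.empty(K)
    for j in range(K):
        delta[j] = logpi[j] + logB[0, j]
    psi = np.zeros((N, K), dtype=np.int64)
    new = np.empty(K)
    for t in range(1, N):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            new[j] = best + logB[t, j]
            psi[t, j] = arg
        for j in range(K):
            delta[j] = new[j]
    path = np.empty(N, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(K):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[N - 1] = arg
    for t in range(N - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
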