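"""Numba-compiled HMM recursions (log-space forward, backward, Viterbi).

All kernels take the per-sequence log initial distribution (N,), a stack of
log transition matrices (T-1, N, N) — constant matrices are tiled by the
caller — and the log observation densities (T, N).  Log-sum-exp is applied
at every step, so arbitrarily long 1 Hz sequences stay stable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logsumexp1d(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - m)
    return m + np.log(s)


@njit(cache=True)
def forward_loglik(log_delta, log_gamma, log_b):
    """Log-likelihood of one observation sequence by the forward recursion."""
    T, N = log_b.shape
    alpha = log_delta + log_b[0]
    work = np.empty(N)
    new = np.empty(N)
    for t in range(1, T):
        for j in range(N):
            for i in range(N):
                work[i] = alpha[i] + log_gamma[t - 1, i, j]
            new[j] = _logsumexp1d(work) + log_b[t, j]
        alpha[:] = new
    return _logsumexp1d(alpha)


@njit(cache=True)
def forward_backward(log_delta, log_gamma, log_b):
    """Smoothing posteriors P(S_t = j | x_{1:T}) and the log-likelihood.

    Returns (posterior (T, N), loglik).  Rows of the posterior sum to one.
    """
    T, N = log_b.shape
    log_alpha = np.empty((T, N))
    log_beta = np.empty((T, N))
    work = np.empty(N)
    log_alpha[0] = log_delta + log_b[0]
    for t in range(1, T):
        for j in range(N):
            for i in range(N):
                work[i] = log_alpha[t - 1, i] + log_gamma[t - 1, i, j]
            log_alpha[t, j] = _logsumexp1d(work) + log_b[t, j]
    log_beta[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        for i in range(N):
            for j in range(N):
                work[j] = log_gamma[t, i, j] + log_b[t + 1, j] + log_beta[t + 1, j]
            log_beta[t, i] = _logsumexp1d(work)
    loglik = _logsumexp1d(log_alpha[T - 1])
    post = np.empty((T, N))
    for t in range(T):
        for j in range(N):
            work[j] = log_alpha[t, j] + log_beta[t, j]
        norm = _logsumexp1d(work)
        for j in range(N):
            post[t, j] = np.exp(work[j] - norm)
    return post, loglik


@njit(cache=True)
def viterbi_path(log_delta, log_gamma, log_b):
    """Most probable state sequence; ties resolved toward the lower index."""
    T, N = log_b.shape
    score = log_delta + log_b[0]
    back = np.empty((T, N), dtype=np.int64)
    new = np.empty(N)
    for t in range(1, T):
        for j in range(N):
            best_i = 0
            best = score[0] + log_gamma[t - 1, 0, j]
            for i in range(1, N):
                v = score[i] + log_gamma[t - 1, i, j]
                if v > best:  # strict: ties keep the lower index
                    best = v
                    best_i = i
            back[t, j] = best_i
            new[j] = best + log_b[t, j]
        score[:] = new
    path = np.empty(T, dtype=np.int64)
    best_j = 0
    best = score[0]
    for j in range(1, N):
        if score[j] > best:
            best = score[j]
            best_j = j
    path[T - 1] = best_j
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
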