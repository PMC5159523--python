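"""Numba-compiled forward-backward and Viterbi kernels.

The recursions are inherently sequential in time, so they are compiled;
everything else in the variational-Bayes loop is vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=False)
def forward_backward(pi_t, a_t, b):
    """Scaled forward-backward with (possibly unnormalized) parameters.

    pi_t : (K,) exp of expected log initial probabilities
    a_t  : (K, K) exp of expected log transition probabilities
    b    : (T, K) exp of expected log emission densities

    Returns (gamma, xi_sum, ln_z): per-frame state responsibilities,
    summed two-slice responsibilities and the log normalizer.
    """
    t_len, k = b.shape
    alpha = np.empty((t_len, k))
    c = np.empty(t_len)

    tmp = pi_t * b[0]
    c[0] = tmp.sum()
    alpha[0] = tmp / c[0]
    for t in range(1, t_len):
        for j in range(k):
            s = 0.0
            for i in range(k):
                s += alpha[t - 1, i] * a_t[i, j]
            tmp[j] = s * b[t, j]
        c[t] = tmp.sum()
        alpha[t] = tmp / c[t]

    beta = np.empty((t_len, k))
    beta[t_len - 1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        for i in range(k):
            s = 0.0
            for j in range(k):
                s += a_t[i, j] * bb[j]
            beta[t, i] = s / c[t + 1]
        for i in range(k):
            for j in range(k):
                xi_sum[i, j] += alpha[t, i] * a_t[i, j] * bb[j] / c[t + 1]

    gamma = alpha * beta
    for t in range(t_len):
        gamma[t] /= gamma[t].sum()
    return gamma, xi_sum, np.log(c).sum()


@njit(fastmath=False)
def viterbi(log_pi, log_a, log_b):
    """Most-probable state path; ties resolve to the lowest state index."""
    t_len, k = log_b.shape
    delta = log_pi + log_b[0]
    psi = np.zeros((t_len, k), dtype=np.int64)
    for t in range(1, t_len):
        new = np.empty(k)
        for j in range(k):
            best_i, best_v = 0, delta[0] + log_a[0, j]
            for i in range(1, k):
                v = delta[i] + log_a[i, j]
                if v > best_v:
                    best_i, best_v = i, v
            psi[t, j] = best_i
            new[j] = best_v + log_b[t, j]
        delta = new
    path = np.empty(t_len, dtype=np.int64)
    best = 0
    for i in range(1, k):
        if delta[i] > delta[best]:
            best = i
    path[t_len - 1] = best
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
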