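"""Scaled forward-backward recursions over sessioned sequences.

The recursion is sequential in time, so it is compiled with numba when
available; a pure-NumPy loop serves as fallback.  Inputs are shifted
likelihoods ``b`` (each row divided by its maximum, so entries are in
(0, 1]), a transition weight matrix ``A`` and initial weights ``pi``
(both may be sub-stochastic: variational inference passes
``exp(E[log theta])``), and a boolean mask marking the first time point
of each session, where the recursion restarts from ``pi``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _fb_kernel(b, A, pi, starts):  # pragma: no cover - exercised via wrapper
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    for t in range(T):
        if starts[t]:
            for k in range(K):
                alpha[t, k] = pi[k] * b[t, k]
        else:
            for k in range(K):
                s = 0.0
                for j in range(K):
                    s += alpha[t - 1, j] * A[j, k]
                alpha[t, k] = s * b[t, k]
        ct = 0.0
        for k in range(K):
            ct += alpha[t, k]
        c[t] = ct
        for k in range(K):
            alpha[t, k] /= ct

    beta = np.empty((T, K))
    gamma = np.empty((T, K))
    for t in range(T - 1, -1, -1):
        if t == T - 1 or starts[t + 1]:
            for k in range(K):
                beta[t, k] = 1.0
        else:
            for j in range(K):
                s = 0.0
                for k in range(K):
                    s += A[j, k] * b[t + 1, k] * beta[t + 1, k]
                beta[t, j] = s / c[t + 1]
        g = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            g += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= g

    xi = np.zeros((K, K))
    for t in range(1, T):
        if not starts[t]:
            for j in range(K):
                for k in range(K):
                    xi[j, k] += alpha[t - 1, j] * A[j, k] * b[t, k] * beta[t, k] / c[t]

    logc = 0.0
    for t in range(T):
        logc += np.log(c[t])
    return gamma, xi, logc


def _fb_numpy(b, A, pi, starts):
    """Reference NumPy implementation (same recursion, vectorized over K)."""
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    for t in range(T):
        a = pi * b[t] if starts[t] else (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    for t in range(T - 1, -1, -1):
        if t == T - 1 or starts[t + 1]:
            beta[t] = 1.0
        else:
            beta[t] = A @ (b[t + 1] * beta[t + 1]) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((K, K))
    for t in range(1, T):
        if not starts[t]:
            xi += np.outer(alpha[t - 1], b[t] * beta[t]) * A / c[t]
    return gamma, xi, float(np.log(c).sum())


def forward_backward(b, A, pi, starts):
    """Run scaled forward-backward; returns ``(gamma, xi, log_c_sum)``.

    ``gamma`` is the (T, K) posterior state probability matrix, ``xi``
    the (K, K) expected transition counts aggregated over within-session
    steps, and ``log_c_sum`` the summed log scaling constants (the log
    normalizer of the sub-normalized chain).
    """
    b = np.ascontiguousarray(b, dtype=np.float64)
    A = np.ascontiguousarray(A, dtype=np.float64)
    pi = np.ascontiguousarray(pi, dtype=np.float64)
    starts = np.ascontiguousarray(starts, dtype=np.bool_)
    fn = _fb_kernel if _HAVE_NUMBA else _fb_numpy
    gamma, xi, logc = fn(b, A, pi, starts)
    if not np.isfinite(logc):
        raise FloatingPointError(
            "forward-backward underflow not rescued by scaling; "
            "inputs are pathological"
        )
    return gamma, xi, logc
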