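"""Exact hypergeometric tail probabilities, vectorised with numba.

A word-enrichment landscape needs millions of exact tail evaluations
(one per word per cutpoint).  The generic discrete-distribution machinery
in scipy sums the pmf from the support edge and is far too slow at that
scale, so the tails are computed here by direct log-space summation with
a ratio recurrence, always starting at the observed count and moving away
from the distributional mode so the terms are decreasing.  No normal or
saddlepoint approximation is involved; the summation is exact up to a
relative truncation tolerance of 1e-17 per tail.

All functions take the parameterisation
    X ~ Hypergeometric(N, K, n)
with N the population size, K the successes in the population and n the
number of draws.
"""

import math

import numpy as np
from numba import njit

_RTOL = 1e-17


@njit(cache=True)
def _logpmf(x, N, K, n):
    return (
        math.lgamma(K + 1) - math.lgamma(x + 1) - math.lgamma(K - x + 1)
        + math.lgamma(N - K + 1) - math.lgamma(n - x + 1)
        - math.lgamma(N - K - n + x + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )


@njit(cache=True)
def _log_upper_from(k, N, K, n):
    """log P[X >= k], summing upward from k; caller ensures k is at or
    above the mode so the terms decrease."""
    xmax = min(K, n)
    if k > xmax:
        return -np.inf
    lt0 = _logpmf(k, N, K, n)
    s = 1.0
    term = 1.0
    x = k
    while x < xmax:
        r = (K - x) * (n - x) / ((x + 1.0) * (N - K - n + x + 1.0))
        term *= r
        s += term
        x += 1
        if r < 1.0 and term < _RTOL * s:
            break
    return lt0 + math.log(s)


@njit(cache=True)
def _log_lower_from(k, N, K, n):
    """log P[X <= k], summing downward from k; caller ensures k is at or
    below the mode."""
    xmin = max(0, n + K - N)
    if k < xmin:
        return -np.inf
    lt0 = _logpmf(k, N, K, n)
    s = 1.0
    term = 1.0
    x = k
    while x > xmin:
        r = (x * (N - K - n + x)) / ((K - x + 1.0) * (n - x + 1.0))
        term *= r
        s += term
        x -= 1
        if r < 1.0 and term < _RTOL * s:
            break
    return lt0 + math.log(s)


@njit(cache=True)
def log_tails(kobs, N, K, n):
    """Return (log P[X >= kobs], log P[X <= kobs]) exactly.

    Each tail is evaluated by summing on the short side of the mode; the
    long side is obtained as the complement so that accuracy is retained
    for probabilities near 1 without long summations.
    """
    xmin = max(0, n + K - N)
    xmax = min(K, n)
    mode = int((n + 1.0) * (K + 1.0) / (N + 2.0))
    if mode < xmin:
        mode = xmin
    if mode > xmax:
        mode = xmax

    # upper tail P[X >= kobs]
    if kobs <= xmin:
        lpe = 0.0
    elif kobs > xmax:
        lpe = -np.inf
    elif kobs > mode:
        lpe = _log_upper_from(kobs, N, K, n)
    else:
        lq = _log_lower_from(kobs - 1, N, K, n) if kobs - 1 >= xmin else -np.inf
        lpe = 0.0 if lq == -np.inf else math.log1p(-math.exp(lq))

    # lower tail P[X <= kobs]
    if kobs >= xmax:
        lpd = 0.0
    elif kobs < xmin:
        lpd = -np.inf
    elif kobs < mode:
        lpd = _log_lower_from(kobs, N, K, n)
    else:
        lq = _log_upper_from(kobs + 1, N, K, n)
        lpd = 0.0 if lq == -np.inf else math.log1p(-math.exp(lq))

    return lpe, lpd


@njit(cache=True)
def signed_scores(kobs, N, K, n, cap):
    """Signed -log10 significance per element.

    Positive when the upper (enrichment) tail is the smaller one,
    negative when the lower (depletion) tail is, zero on ties; magnitude
    clipped at ``cap``.
    """
    out = np.empty(kobs.size)
    ln10 = math.log(10.0)
    for i in range(kobs.size):
        lpe, lpd = log_tails(kobs[i], N[i], K[i], n[i])
        if lpe < lpd:
            v = -lpe / ln10
        elif lpd < lpe:
            v = lpd / ln10
        else:
            v = 0.0
        if v > cap:
            v = cap
        elif v < -cap:
            v = -cap
        out[i] = v
    return out


def upper_tail_p(kobs, N, K, n):
    """Exact P[X >= kobs] for scalar arguments (convenience wrapper)."""
    lpe, _ = log_tails(int(kobs), int(N), int(K), int(n))
    return math.exp(lpe)


def lower_tail_p(kobs, N, K, n):
    """Exact P[X <= kobs] for scalar arguments (convenience wrapper)."""
    _, lpd = log_tails(int(kobs), int(N), int(K), int(n))
    return math.exp(lpd)
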