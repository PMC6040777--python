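"""Exact upper tail of the Poisson binomial distribution.

The Poisson binomial is the distribution of a sum of independent Bernoulli
trials with unequal success probabilities.  The tail P(X >= k) is computed by
a dynamic-programming convolution with an absorbing bin at k: the state vector
holds P(X_t = j) for j < k plus the already-absorbed mass P(X_t >= k), so the
tail accumulates as a sum of positive terms and stays accurate even when it is
very small (no 1 - P catastrophic cancellation).  Cost is O(n * min(k, n)).

Above a configurable work threshold the refined normal approximation (a
skewness-corrected Edgeworth/Cornish-Fisher form) is used instead; this is a
documented fallback intended for n on the order of 10^6 trials.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InputError

#: Switch to the refined normal approximation when n * min(k, n) exceeds this.
EXACT_WORK_LIMIT = 2 * 10**8


def _refined_normal_tail(p: np.ndarray, k: int) -> float:
    """Refined normal approximation to P(X >= k) with continuity and skewness
    corrections (Volkova-style)."""
    mu = p.sum()
    var = (p * (1 - p)).sum()
    if var == 0:
        return float(k <= mu)
    sigma = np.sqrt(var)
    gamma = (p * (1 - p) * (1 - 2 * p)).sum() / sigma**3
    x = (k - 0.5 - mu) / sigma
    phi = stats.norm.pdf(x)
    tail = stats.norm.sf(x) - gamma * (1 - x**2) * phi / 6.0
    return float(min(1.0, max(0.0, tail)))


def poisson_binomial_tail(probabilities, k: int, *, exact: bool | None = None) -> float:
    """P(X >= k) for X a sum of independent Bernoulli(p_i) trials.

    Parameters
    ----------
    probabilities : array-like of float in [0, 1]
        Per-trial success probabilities.
    k : int
        Tail threshold, 0 <= k <= n + 1 (k = 0 gives 1, k = n + 1 gives 0).
    exact : bool, optional
        Force the exact DP (True) or the refined-normal fallback (False);
        by default chosen from the work estimate.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise InputError("success probabilities must lie in [0, 1]")
    n = p.size
    if not 0 <= k <= n + 1:
        raise InputError(f"k = {k} outside 0..{n + 1}")
    if k == 0:
        return 1.0
    if k > n:
        return 0.0
    if exact is None:
        exact = n * min(k, n) <= EXACT_WORK_LIMIT
    if not exact:
        return _refined_normal_tail(p, k)

    # state[j] = P(X = j and never reached k); absorbed = P(X >= k so far)
    state = np.zeros(k, dtype=float)
    state[0] = 1.0
    absorbed = 0.0
    for pi in p:
        if pi == 0.0:
            continue
        absorbed += state[k - 1] * pi
        state[1:] = state[1:] * (1.0 - pi) + state[:-1] * pi
        state[0] *= 1.0 - pi
    return float(absorbed)


def poisson_binomial_pmf(probabilities) -> np.ndarray:
    """Full PMF over 0..n by direct convolution (intended for modest n)."""
    p = np.asarray(probabilities, dtype=float).ravel()
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise InputError("success probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf
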