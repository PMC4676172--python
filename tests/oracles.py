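"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by direct enumeration or a
textbook formula, deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import math

import numpy as np


def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """Textbook 1-df Hardy-Weinberg chi-square test p-value."""
    from scipy.stats import chi2

    n = n0 + n1 + n2
    p = (n1 + 2 * n2) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    keep = exp > 0
    stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    return float(chi2.sf(stat, 1))


def welch_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Hand-computed Welch two-sample t-test p-value."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(2 * tdist.sf(abs(t), df))


def poisson_upper_tail(k: int, lam: float, terms: int = 4000) -> float:
    """P(X >= k) for X ~ Poisson(lam) by direct summation."""
    logs = []
    for i in range(k, k + terms):
        logs.append(-lam + i * math.log(lam) - math.lgamma(i + 1))
    m = max(logs)
    return math.exp(m) * sum(math.exp(v - m) for v in logs)


def nb_logpmf(k: int, mean: float, phi: float) -> float:
    """NB log pmf with variance = mean + phi * mean^2, via lgamma."""
    r = 1.0 / phi
    p = r / (r + mean)
    return (
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log1p(-p)
    )


def nb_exact_p(k_a: int, k_b: int, s_a: float, s_b: float, phi: float) -> float:
    """Exhaustive sum-conditioned NB exact test for small totals."""
    total = k_a + k_b
    if total == 0:
        return 1.0
    mu = (k_a / s_a + k_b / s_b) / 2.0
    probs = np.array(
        [
            math.exp(nb_logpmf(a, mu * s_a, phi) + nb_logpmf(total - a, mu * s_b, phi))
            for a in range(total + 1)
        ]
    )
    obs = probs[k_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-10)].sum() / probs.sum()))


def efron_partial_loglik(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Efron partial log-likelihood evaluated on a grid of beta (1 covariate).

    Direct textbook implementation: explicit risk sets per event time.
    ``beta`` may be a vector of values; returns one log-likelihood each.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    x = np.asarray(X, float).reshape(-1)
    ll = np.zeros(len(beta))
    theta = np.exp(np.outer(beta, x))  # (grid, n)
    for u in np.unique(times[events == 1]):
        risk = times >= u
        dead = (times == u) & (events == 1)
        d = int(dead.sum())
        s_risk = theta[:, risk].sum(axis=1)
        s_dead = theta[:, dead].sum(axis=1)
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_dead)
    return ll


def three_segment_rss(x: np.ndarray, i: int, j: int) -> float:
    """Residual sum of squares of a 3-mean fit split at i and j."""
    parts = [x[:i], x[i:j], x[j:]]
    return float(sum(((p - p.mean()) ** 2).sum() for p in parts))


def best_two_breakpoints(x: np.ndarray, min_bins: int) -> tuple[int, int]:
    """Exhaustive search over all split pairs minimizing the 3-segment RSS."""
    n = len(x)
    best, arg = np.inf, None
    for i in range(min_bins, n - 2 * min_bins + 1):
        for j in range(i + min_bins, n - min_bins + 1):
            r = three_segment_rss(x, i, j)
            if r < best:
                best, arg = r, (i, j)
    return arg


def km_survival_no_censoring(times: np.ndarray) -> dict[float, float]:
    """Empirical survival function S(t) = P(T > t) at each event time."""
    times = np.sort(np.asarray(times, float))
    return {float(t): float((times > t).mean()) for t in np.unique(times)}
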