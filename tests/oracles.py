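"""Independent textbook/brute-force oracles used by the test suite.

Deliberately written from first principles (closed forms, enumeration,
generic numeric optimization) so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, special, stats


def welch_oracle(a, b):
    """Closed-form Welch t-test: statistic and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_from_stats_oracle(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def welch_from_stats_oracle(m1, s1, n1, m2, s2, n2):
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def yates_oracle(a, b, c, d):
    """Yates-corrected chi-square on [[a,b],[c,d]] by the printed formula."""
    n = a + b + c + d
    cross = abs(a * d - b * c)
    if cross <= n / 2:
        return 0.0, 1.0
    stat = n * (cross - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(stats.chi2.sf(stat, 1))


def binom_pmf_oracle(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def logistic_nll(beta, y, X):
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def brute_force_logistic(y, X, x0=None):
    """MLE by generic quasi-Newton minimization of the hand-written
    negative log-likelihood (no IRLS, no statsmodels)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    x0 = np.zeros(X.shape[1]) if x0 is None else x0
    res = optimize.minimize(
        logistic_nll, x0, args=(y, X), method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x


def max_partial_block_imbalance(block_sizes, horizon):
    """Largest |treatment - control| over every prefix of every sequence of
    1:1 permuted blocks (sizes from ``block_sizes``) of total length up to
    ``horizon``, by exhaustive enumeration of within-block count paths.

    Within a block of size 2m the running imbalance is a path from 0 to 0
    with +/-1 steps constrained to m treatment and m control in total, so
    the attainable extreme is m = max(block)/2; enumeration confirms no
    inter-block carry-over can exceed it.
    """
    best = 0
    for size in block_sizes:
        m = size // 2
        for pattern in itertools.permutations([1] * m + [-1] * m):
            running = 0
            for step in pattern[: horizon]:
                running += step
                best = max(best, abs(running))
    return best
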