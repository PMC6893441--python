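"""Independent brute-force oracles used to validate the statistical kernels.

Each oracle implements the defining formula directly (exact integer
arithmetic or explicit enumeration), with no shared code with the package
implementations it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def bh_stepup_oracle(pvals):
    """q_(i) = min_{j >= i} m * p_(j) / j, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bh_reject_oracle(pvals, alpha):
    """Classic BH step-up rejection set at level alpha (boolean mask)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= alpha * rank / m:
            k = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration.

    Integer arithmetic throughout: table probabilities share the
    denominator C(n, r1), so the probability-mass comparison reduces to
    comparing integer numerators C(c1, k) * C(c2, r1 - k).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    c2 = n - c1
    k_min, k_max = max(0, r1 - c2), min(r1, c1)
    weights = {k: comb(c1, k) * comb(c2, r1 - k) for k in range(k_min, k_max + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, comb(n, r1)))


def mwu_exact_two_sided_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Requires tie-free data.  U is counted for x; the two-sided p doubles
    the smaller tail (capped at 1), matching the exact-distribution
    convention.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle needs tie-free data"
    nx = x.size
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(pooled.size), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.asarray(us)
    total = us.size
    p_le = np.count_nonzero(us <= u_obs) / total
    p_ge = np.count_nonzero(us >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
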