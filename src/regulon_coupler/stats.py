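"""Statistical kernels used across the pipeline.

Thin, strictly-validated wrappers around scipy/statsmodels with the exact
conventions the pipeline depends on:

* Pearson r with a two-sided p-value from the t transform
  ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom;
* Benjamini-Hochberg step-up q-values (``q < alpha`` reproduces the classic
  BH rejection set at level ``alpha``);
* two-sided Fisher's exact test under the probability-mass rule, with the
  sample odds ratio ``a*d / (b*c)``;
* Mann-Whitney U with midrank ties, exact by enumeration for small
  tie-free samples and a continuity-corrected normal approximation
  otherwise;
* Bonferroni adjustment ``min(1, m*p)``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

__all__ = [
    "pearson_with_p",
    "pearson_rows",
    "bh_fdr",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "bonferroni",
]

# both groups at or below this size (and tie-free) -> exact Mann-Whitney
_MWU_EXACT_MAX_N = 8


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    Pairs with a missing value in either vector are removed first; at least
    three complete pairs and non-zero variance in both vectors are required.
    ``|r| = 1`` returns ``p = 0`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson_with_p: vectors differ in length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValidationError(f"pearson_with_p: only {n} complete pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_with_p: zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    # exactly collinear input can round to just under |r| = 1; apply the
    # |r| = 1 -> p = 0 convention within machine precision of the bound
    if abs(r) >= 1.0 - 1e-15:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def pearson_rows(
    x: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation of ``x`` against every row of ``Y`` at once.

    Missing values are removed pairwise per row.  Returns ``(r, p, n_used)``
    arrays; rows with fewer than three complete pairs or zero variance get
    NaN.  p-values come from the t transform on ``n_used - 2`` df and agree
    with :func:`pearson_with_p` (cross-checked in the test suite).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xfin = np.isfinite(x)
    if xfin.all() and np.isfinite(Y).all():
        n_used = np.full(Y.shape[0], x.size)
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum())
        sy = np.sqrt((Yc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Yc @ xc) / (sy * sx)
    else:
        r = np.empty(Y.shape[0])
        n_used = np.empty(Y.shape[0], dtype=int)
        for i, row in enumerate(Y):
            m = xfin & np.isfinite(row)
            n_used[i] = m.sum()
            if n_used[i] < 3:
                r[i] = np.nan
                continue
            xi, yi = x[m], row[m]
            xc, yc = xi - xi.mean(), yi - yi.mean()
            denom = np.sqrt((xc**2).sum() * (yc**2).sum())
            r[i] = (xc @ yc) / denom if denom > 0 else np.nan
    r = np.clip(r, -1.0, 1.0)
    df = np.maximum(n_used - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0 - 1e-15, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p, n_used


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j``; declaring ``q < alpha``
    reproduces the classic BH rejection set at level ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("bh_fdr: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table ``[[a, b], [c, d]]``.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table (probability-mass rule).  The odds ratio is the sample estimate
    ``a*d / (b*c)``, infinite when ``b*c == 0`` and ``a*d > 0``, NaN for
    doubly degenerate tables.
    """
    cells = (a, b, c, d)
    for v in cells:
        if v < 0 or v != int(v):
            raise ValidationError(f"fisher_exact_2x2: cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    if a + b + c + d == 0:
        raise ValidationError("fisher_exact_2x2: empty table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of rank configurations) when both
    groups have at most eight observations and there are no ties; otherwise
    the normal approximation with tie-corrected variance and continuity
    correction is used.  Returns ``(U, p)`` with U counted for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u: both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if not ties and x.size <= _MWU_EXACT_MAX_N and y.size <= _MWU_EXACT_MAX_N:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m*p)``; ``m`` defaults to ``len(pvals)``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("bonferroni: p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"bonferroni: family size {m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)
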