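"""Exact binomial scoring of allelic imbalance with FDR control.

Under the null hypothesis of equal coverage of the two alleles, the number
of G1-supporting reads at a site with n informative reads is
Binomial(n, 1/2).  Each counted SNP gets an exact two-sided p-value
(minimum-likelihood method), p-values are adjusted with the
Benjamini–Hochberg step-up, and sites with q below alpha are selected as
allele-specific (AS-SNPs).
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np
from scipy import stats

from .model import AlleleCountRecord, ASTestResult

#: Relative slack on the density comparison; guards against floating-point
#: ties between binomial pmf values at symmetric outcomes.
_PMF_SLACK = 1e-7


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood method.

    Sums P(X = i) over every outcome i whose probability does not exceed
    P(X = k) (up to a 1e-7 relative slack), i.e. every outcome at least as
    extreme as the observed one in likelihood.  For p0 = 0.5 this reduces
    to the familiar symmetric two-tail sum.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly between 0 and 1")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    thresh = pmf[k] * (1.0 + _PMF_SLACK)
    if thresh >= pmf.max():  # observed outcome is the mode: every outcome counts
        return 1.0
    p = float(pmf[pmf <= thresh].sum())
    return min(1.0, p)


def binom_two_sided_many(k: Sequence[int], n: Sequence[int], p0: float = 0.5) -> np.ndarray:
    """Vectorised :func:`binom_two_sided` over paired (k, n) arrays.

    Groups sites by n so each pmf vector is computed once — the depth
    distribution in ChIP-seq data is narrow, making this near-linear.
    """
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    out = np.empty(len(k), dtype=float)
    for nv in np.unique(n):
        idx = np.flatnonzero(n == nv)
        pmf = stats.binom.pmf(np.arange(nv + 1), int(nv), p0)
        pmf_max = pmf.max()
        thresh = pmf[k[idx]] * (1.0 + _PMF_SLACK)
        # same masked summation order as the scalar path, so the two agree bitwise
        out[idx] = [
            1.0 if t >= pmf_max else min(1.0, float(pmf[pmf <= t].sum()))
            for t in thresh
        ]
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over ranks j >= i of p_(j) * m / j, capped at 1; input
    order is preserved in the output.  Ties share the larger rank's
    quotient before the running minimum, per the standard step-up.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_binomial_tests(
    records: Iterable[AlleleCountRecord],
    alpha: float = 0.05,
    method: str = "bh",
) -> List[ASTestResult]:
    """Score every counted SNP and flag selections.

    ``method="bh"`` (default) selects on BH-adjusted q < alpha, matching a
    selection performed after multiple-testing correction; ``method="raw"``
    selects on the unadjusted p-value, available for comparison.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if method not in ("bh", "raw"):
        raise ValueError(f"unknown correction method {method!r}")
    recs = list(records)
    if not recs:
        return []
    p = binom_two_sided_many(
        [r.n_g1 for r in recs], [r.n_total_informative for r in recs]
    )
    q = bh_adjust(p)
    crit = p if method == "raw" else q
    return [
        ASTestResult(
            snp=r.snp,
            n_g1=r.n_g1,
            n_g2=r.n_g2,
            p_value=float(pi),
            q_value=float(qi),
            selected=bool(ci < alpha or alpha >= 1.0),
        )
        for r, pi, qi, ci in zip(recs, p, q, crit)
    ]


def select_as_snps(
    results: Iterable[ASTestResult], alpha: float = 0.05
) -> List[ASTestResult]:
    """The AS-SNP call set: results with q < alpha.

    Sorted by q-value, then by distance of the allelic ratio from 0.5
    (strongest imbalance first).  ``alpha = 1.0`` is the vacuous threshold:
    every result is selected even though q-values are capped at 1.
    """
    picked = [r for r in results if r.q_value < alpha or alpha >= 1.0]
    picked.sort(key=lambda r: (r.q_value, -abs(r.allelic_ratio - 0.5)))
    return [
        r if r.selected else ASTestResult(r.snp, r.n_g1, r.n_g2, r.p_value, r.q_value, True)
        for r in picked
    ]
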