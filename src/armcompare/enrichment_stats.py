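"""Exact 2x2 association tests and category enrichment with BH control.

The exact test conditions on the table margins (hypergeometric model)
and computes the two-sided p-value as the sum of point probabilities no
larger than the observed one (the common "small-likelihood" rule), in
log space for stability, with a 1e-7 relative tolerance guarding
against floating-point ties.  Category enrichment uses the subset
construction — the foreground is removed from the background before
testing — and adjusts across tested categories by Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_REL_TOL = 1e-7


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int   # category hits in foreground
    n: int   # foreground size
    K: int   # category hits in background
    N: int   # background size
    odds_ratio: float
    p: float
    p_adj: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided exact test and sample odds ratio for one 2x2 table.

    Cells are (a, b // c, d).  Margins with a zero row/column make the
    table degenerate; p = 1 is returned with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    odds = (a * d / (b * c)) if b * c > 0 else float("inf")
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0, odds

    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    # log P(X = k) under the central hypergeometric distribution
    logp = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    obs = logp[a - lo]
    keep = logp <= obs + np.log1p(_REL_TOL)
    # log-sum-exp over the kept tables
    m = logp[keep].max()
    p = float(np.exp(m) * np.exp(logp[keep] - m).sum())
    return min(1.0, p), odds


def subset_table(k: int, n: int, K: int, N: int) -> tuple[int, int, int, int]:
    """2x2 cells for a foreground that is a subset of the background.

    Returns (k, n-k, K-k, N-n-(K-k)): the background rows exclude the
    foreground, so the two rows are disjoint.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent subset counts k={k} n={n} K={K} N={N}")
    d = (N - n) - (K - k)
    if d < 0:
        raise ValueError("category hits exceed background remainder")
    return k, n - k, K - k, d


def category_enrichment(foreground: Sequence[str], background: Sequence[str],
                        annotation: Mapping[str, Sequence[str]],
                        method: str = "BH") -> list[EnrichmentResult]:
    """One exact test per category with >= 1 foreground hit, BH-adjusted.

    ``annotation`` maps gene id -> category labels.  The foreground must
    be a subset of the background.
    """
    if method != "BH":
        raise ValueError("only Benjamini-Hochberg adjustment is supported")
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground is not a subset of the background")

    cat_fg: dict[str, int] = {}
    cat_bg: dict[str, int] = {}
    for gene in bg:
        for cat in annotation.get(gene, ()):  # genes may be unannotated
            cat_bg[cat] = cat_bg.get(cat, 0) + 1
            if gene in fg:
                cat_fg[cat] = cat_fg.get(cat, 0) + 1

    tested = sorted(cat for cat, cnt in cat_fg.items() if cnt >= 1)
    if not tested:
        return []
    n, N = len(fg), len(bg)
    raw = []
    for cat in tested:
        k, K = cat_fg[cat], cat_bg[cat]
        a, b, c, d = subset_table(k, n, K, N)
        p, odds = fisher_exact_2x2(a, b, c, d)
        raw.append((cat, k, K, p, odds))
    _, p_adj, _, _ = multipletests([r[3] for r in raw], method="fdr_bh")
    results = [
        EnrichmentResult(cat, k, n, K, N, odds, p, float(q))
        for (cat, k, K, p, odds), q in zip(raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.category))
    return results
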