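"""Shared enrichment statistics: one-sided tail tests and BH adjustment.

All tests are upper-tail ("at least the observed count"), the convention
for over-representation: the observed count itself is included in the
tail, so an observed count of zero always gives p = 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("need 0 <= successes, draws <= population")
    if k > min(successes, draws):
        raise ValueError(
            f"observed overlap {k} exceeds min(successes={successes}, draws={draws})"
        )
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, population, successes, draws))


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]
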