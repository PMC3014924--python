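"""Hypergeometric enrichment tests for positional zones and gene sets.

Zone enrichment asks whether LOMBs are over-represented in a positional zone
relative to the all-bins background: with N total bins, K bins in the zone,
n LOMBs and x LOMBs in the zone, the upper-tail hypergeometric probability
P(X >= x) is computed exactly and Bonferroni-corrected over the six zones.
Fold enrichment is (x/n)/(K/N).  A global chi-squared statistic compares the
full LOMB zone distribution against the background distribution scaled to
the LOMB total (5 degrees of freedom).

Gene-set overlap uses the same tail probability with gene counts; a battery
of such tests can be corrected by Benjamini-Hochberg instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chisquare, hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import ZONES

N_ZONES = len(ZONES)


@dataclass
class OverlapTest:
    """One hypergeometric overlap test between two sets in a universe."""

    N: int
    K: int
    n: int
    x: int
    p: float

    def to_dict(self) -> dict:
        return {"N": self.N, "K": self.K, "n": self.n, "x": self.x, "p": self.p}


def hypergeom_tail(N: int, K: int, n: int, x: int, lower: bool = False) -> float:
    """Exact hypergeometric tail P(X >= x) (or P(X <= x) with ``lower``)
    under sampling n from a universe of N containing K category members.

    Accumulated in log space over the support for numerical stability at
    extreme tails.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid parameters N={N}, K={K}, n={n}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"x={x} outside [0, min(K, n)={min(K, n)}]")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    ks = np.arange(lo, x + 1) if lower else np.arange(x, hi + 1)
    if not len(ks):
        return 0.0
    return float(min(1.0, np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n)))))


@dataclass
class ZoneEnrichmentResult:
    """Per-zone enrichment table plus the global chi-squared comparison."""

    table: pd.DataFrame
    chi2: float
    chi2_p: float
    chi2_df: int


def zone_enrichment(lomb_zone_counts: Sequence[int],
                    all_zone_counts: Sequence[int],
                    lower: bool = False) -> ZoneEnrichmentResult:
    """Test each of the six zones for LOMB enrichment against the all-bins
    background; Bonferroni-correct over the six tests.

    ``lower=True`` tests depletion (lower tail) instead of enrichment.
    """
    obs = np.asarray(lomb_zone_counts, dtype=np.int64)
    bg = np.asarray(all_zone_counts, dtype=np.int64)
    if obs.shape != (N_ZONES,) or bg.shape != (N_ZONES,):
        raise ValueError(f"expected {N_ZONES} counts per distribution")
    if (obs > bg).any():
        raise ValueError("zone LOMB count exceeds background bin count")
    n, N = int(obs.sum()), int(bg.sum())
    if n <= 0 or N <= 0:
        raise ValueError("totals must be positive")
    if ((bg == 0) & (obs > 0)).any():
        raise ValueError("zero background in a zone with LOMBs")

    rows = []
    for zone, x, K in zip(ZONES, obs, bg):
        expected = n * K / N
        fold = (x / n) / (K / N) if K else np.nan
        p = hypergeom_tail(N, int(K), n, int(x), lower=lower)
        rows.append((zone, int(x), int(K), expected, fold, p, min(1.0, N_ZONES * p)))
    table = pd.DataFrame(rows, columns=["zone", "observed", "background",
                                        "expected", "fold", "p_raw", "p_bonferroni"])
    expected_full = bg * (n / N)
    nz = expected_full > 0
    chi2, chi2_p = chisquare(obs[nz], expected_full[nz])
    return ZoneEnrichmentResult(table, float(chi2), float(chi2_p), int(nz.sum() - 1))


def geneset_overlap(set_a: Iterable[str], set_b: Iterable[str],
                    universe: Iterable[str]) -> OverlapTest:
    """Upper-tail hypergeometric test of the overlap between two gene sets
    within a universe (both sets must be subsets of the universe)."""
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    N, K, n = len(universe), len(a), len(b)
    x = len(a & b)
    return OverlapTest(N, K, n, x, hypergeom_tail(N, K, n, x))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
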