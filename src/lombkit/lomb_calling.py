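"""Per-bin log2 methylation ratios and loss-of-methylation bin (LOMB) calling.

For each retained bin the methylation ratio is wild-type over mutant tag
count (post-equalization), log2-transformed with a pseudocount:

    r_b = log2((wt_b + c) / (mt_b + c))

A bin is retained if it is euchromatic, full width, and carries signal
(wt + mt > 0; with pseudocount 0, mt > 0 as well).  The ratio distribution
is summarized by its arithmetic mean mu and population standard deviation
sigma over retained bins, and bins with r_b strictly greater than
mu + k*sigma (default k = 2) are called LOMBs — bins where methylation is
at least 2^(mu + k*sigma)-fold higher in wild-type than in the mutant.
Bins below mu - k*sigma are the symmetric gain-side calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinCounts, BinGrid

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_K = 2.0


@dataclass
class RatioTable:
    """Per-bin log2 wt/mt ratios with the retained-bin mask.

    ``log2_ratio`` is NaN outside the retained set (partial bins,
    heterochromatic bins, bins excluded by the zero rule).
    """

    grid: BinGrid
    wt_sample: str
    mt_sample: str
    wt: np.ndarray
    mt: np.ndarray
    log2_ratio: np.ndarray
    retained: np.ndarray
    pseudocount: float

    @property
    def retained_ratios(self) -> np.ndarray:
        return self.log2_ratio[self.retained]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class LombSet:
    """Bins beyond mean + k*SD of the log2 ratio distribution.

    ``threshold_fold`` = 2^threshold_log2 is the minimum wt/mt fold change a
    called bin exceeds.
    """

    k: float
    mu: float
    sigma: float
    lomb_bins: np.ndarray
    gain_bins: np.ndarray

    @property
    def threshold_log2(self) -> float:
        return threshold_log2(self.mu, self.sigma, self.k)

    @property
    def threshold_fold(self) -> float:
        return threshold_fold(self.mu, self.sigma, self.k)

    @property
    def n_lomb(self) -> int:
        return len(self.lomb_bins)

    @property
    def n_gain(self) -> int:
        return len(self.gain_bins)


def threshold_log2(mu: float, sigma: float, k: float = DEFAULT_K) -> float:
    """Calling threshold on the log2 scale, mu + k*sigma."""
    return mu + k * sigma


def threshold_fold(mu: float, sigma: float, k: float = DEFAULT_K) -> float:
    """Calling threshold as a wt/mt fold change, 2^(mu + k*sigma)."""
    return float(2.0 ** threshold_log2(mu, sigma, k))


def compute_log_ratios(counts: BinCounts, wt_sample: str, mt_sample: str,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> RatioTable:
    """Log2 (wt+c)/(mt+c) per bin; retention excludes partial and
    heterochromatic bins, bins with wt+mt = 0 and, when c = 0, bins with
    mt = 0 (the ratio would be infinite)."""
    for s in (wt_sample, mt_sample):
        if s not in counts.counts:
            raise KeyError(f"unknown sample {s!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    grid = counts.grid
    wt = counts.counts[wt_sample].astype(float)
    mt = counts.counts[mt_sample].astype(float)
    retained = grid.euchromatic & ~grid.partial & ((wt + mt) > 0)
    if pseudocount == 0:
        retained &= (mt > 0) & (wt > 0)
    ratio = np.full(grid.n_bins, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[retained] = np.log2((wt[retained] + pseudocount)
                                  / (mt[retained] + pseudocount))
    return RatioTable(grid, wt_sample, mt_sample, wt, mt, ratio, retained, pseudocount)


def fit_distribution(ratios: RatioTable) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of the retained
    log2 ratios (no trimming, no robust estimator)."""
    r = ratios.retained_ratios
    if len(r) < 2:
        raise ValueError("need at least 2 retained bins")
    return float(r.mean()), float(r.std(ddof=0))


def call_lombs(ratios: RatioTable, k: float = DEFAULT_K) -> LombSet:
    """Call LOMBs (ratio > mu + k*sigma) and gain bins (ratio < mu - k*sigma).

    Strict inequalities: bins exactly at a threshold are not called.
    """
    mu, sigma = fit_distribution(ratios)
    if sigma == 0:
        raise ValueError("degenerate ratio distribution (sigma = 0)")
    hi = threshold_log2(mu, sigma, k)
    lo = mu - k * sigma
    r = ratios.log2_ratio
    with np.errstate(invalid="ignore"):
        lomb = np.flatnonzero(ratios.retained & (r > hi))
        gain = np.flatnonzero(ratios.retained & (r < lo))
    return LombSet(k, mu, sigma, lomb, gain)


def merge_adjacent(lombs: LombSet, grid: BinGrid) -> pd.DataFrame:
    """Merge genomically adjacent LOMB bins on the same chromosome into
    maximal regions (chrom, start, end, n_bins)."""
    idx = np.sort(lombs.lomb_bins)
    if not len(idx):
        return pd.DataFrame(columns=["chrom", "start", "end", "n_bins"])
    chrom = grid.chrom_index[idx]
    # adjacency: consecutive ordinals on the same chromosome
    brk = np.flatnonzero((np.diff(idx) != 1) | (np.diff(chrom) != 0)) + 1
    names = np.array([c for c, _ in grid.chromosomes], dtype=object)
    rows = []
    for run in np.split(idx, brk):
        rows.append((names[grid.chrom_index[run[0]]],
                     int(grid.start[run[0]]), int(grid.end[run[-1]]), len(run)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins"])


def summarize(ratios: RatioTable, lombs: LombSet) -> dict:
    """Machine-readable calling summary."""
    return {
        "n_retained_bins": ratios.n_retained,
        "mu": lombs.mu,
        "sigma": lombs.sigma,
        "k": lombs.k,
        "threshold_log2": lombs.threshold_log2,
        "threshold_fold": lombs.threshold_fold,
        "n_lomb_bins": lombs.n_lomb,
        "n_gain_bins": lombs.n_gain,
        "lomb_fraction_pct": 100.0 * lombs.n_lomb / max(ratios.n_retained, 1),
    }
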