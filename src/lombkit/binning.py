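"""Fixed-width genome tiling, per-bin tag counting and library equalization.

The genome is tiled into ``width``-bp bins (default 300).  Every genomic
position maps to exactly one bin; the last bin of a chromosome may be
shorter than ``width`` and is flagged partial.  A bin is euchromatic unless
its midpoint falls inside the heterochromatin mask.  Tags are assigned to
the bin containing their interval midpoint.

Library equalization rescales every sample to the smallest library by a
uniform multiplicative factor (deterministic, real-valued counts); a seeded
random-subsampling mode is available for integer workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeModel, TagSet

DEFAULT_BIN_WIDTH = 300


@dataclass
class BinGrid:
    """Ordered fixed-width tiling of all chromosomes.

    Bins are stored as flat arrays in chromosome order; ``offsets[i]`` is the
    ordinal of the first bin of chromosome i.
    """

    width: int
    chromosomes: list[tuple[str, int]]
    chrom_index: np.ndarray     # per bin: index into chromosomes
    start: np.ndarray           # per bin
    end: np.ndarray             # per bin
    euchromatic: np.ndarray     # bool per bin (midpoint outside het mask)
    partial: np.ndarray         # bool per bin (shorter than width)
    offsets: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def chrom_names(self) -> np.ndarray:
        names = np.array([c for c, _ in self.chromosomes], dtype=object)
        return names[self.chrom_index]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def bin_of(self, chrom: str, position: np.ndarray | int) -> np.ndarray | int:
        """Ordinal of the bin containing (chrom, position); -1 if out of range."""
        lengths = dict(self.chromosomes)
        pos = np.asarray(position)
        idx = self.offsets[chrom] + pos // self.width
        ok = (pos >= 0) & (pos < lengths[chrom])
        return np.where(ok, idx, -1) if pos.ndim else (int(idx) if ok else -1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom_names,
            "start": self.start,
            "end": self.end,
            "euchromatic": self.euchromatic,
            "partial": self.partial,
        })


@dataclass
class BinCounts:
    """Per-bin tag counts for one or more samples on a shared grid.

    Counts are non-negative reals (equalization rescales them); ``dropped``
    records tags that fell outside the grid's chromosomes per sample.
    """

    grid: BinGrid
    counts: dict[str, np.ndarray]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    def total(self, sample: str) -> float:
        return float(self.counts[sample].sum())

    def add(self, other: "BinCounts") -> "BinCounts":
        if other.grid is not self.grid and other.grid.n_bins != self.grid.n_bins:
            raise ValueError("grids differ")
        merged = dict(self.counts)
        merged.update(other.counts)
        dropped = dict(self.dropped)
        dropped.update(other.dropped)
        return BinCounts(self.grid, merged, dropped)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        for s, v in self.counts.items():
            df[s] = v
        return df


def make_bins(genome: GenomeModel, width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Tile every chromosome into ceil(length/width) bins and flag each bin's
    chromatin state from the genome's heterochromatin mask."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    chrom_idx, starts, ends = [], [], []
    offsets: dict[str, int] = {}
    total = 0
    for i, (name, length) in enumerate(genome.chromosomes):
        n = -(-length // width)  # ceil
        offsets[name] = total
        s = np.arange(n, dtype=np.int64) * width
        e = np.minimum(s + width, length)
        chrom_idx.append(np.full(n, i, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        total += n
    chrom_index = np.concatenate(chrom_idx)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    partial = (end - start) != width

    euch = np.ones(total, dtype=bool)
    if len(genome.het_mask):
        mid = (start + end) // 2
        names = np.array([c for c, _ in genome.chromosomes], dtype=object)[chrom_index]
        for row in genome.het_mask.itertuples():
            hit = (names == row.chrom) & (mid >= row.start) & (mid < row.end)
            euch[hit] = False
    return BinGrid(width, list(genome.chromosomes), chrom_index, start, end,
                   euch, partial, offsets)


def count_tags(tags: TagSet, grid: BinGrid) -> BinCounts:
    """Assign each tag to the bin containing its interval midpoint,
    floor((start+end)/2).  Count total is conserved: sum of the vector equals
    the number of tags on the grid's chromosomes."""
    vec = np.zeros(grid.n_bins, dtype=float)
    df = tags.tags
    lengths = dict(grid.chromosomes)
    dropped = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid.offsets:
            dropped += len(sub)
            continue
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        ok = (mid >= 0) & (mid < lengths[chrom])
        dropped += int((~ok).sum())
        idx = grid.offsets[chrom] + mid[ok] // grid.width
        np.add.at(vec, idx, 1.0)
    return BinCounts(grid, {tags.sample_id: vec}, {tags.sample_id: dropped})


def count_samples(tagsets: list[TagSet], grid: BinGrid) -> BinCounts:
    """Count several samples onto one grid."""
    out = count_tags(tagsets[0], grid)
    for ts in tagsets[1:]:
        out = out.add(count_tags(ts, grid))
    return out


def equalize_libraries(counts: BinCounts) -> BinCounts:
    """Scale every sample's count vector by (min total / its total) so all
    library totals equal the smallest one; the smallest library is unchanged."""
    totals = {s: counts.total(s) for s in counts.samples}
    if len(totals) < 2:
        raise ValueError("equalization needs at least two samples")
    for s, t in totals.items():
        if t <= 0:
            raise ValueError(f"sample {s!r} has zero total")
    floor = min(totals.values())
    scaled = {s: v * (floor / totals[s]) for s, v in counts.counts.items()}
    return BinCounts(counts.grid, scaled, dict(counts.dropped))


def subsample_libraries(counts: BinCounts, seed: int) -> BinCounts:
    """Integer alternative to multiplicative equalization: randomly downsample
    each sample's tags (per-bin hypergeometric draw) to the smallest total."""
    totals = {s: int(round(counts.total(s))) for s in counts.samples}
    if any(t <= 0 for t in totals.values()):
        raise ValueError("sample with zero total")
    floor = min(totals.values())
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for s, v in counts.counts.items():
        iv = np.round(v).astype(np.int64)
        out[s] = rng.multivariate_hypergeometric(iv, floor).astype(float) \
            if totals[s] > floor else iv.astype(float)
    return BinCounts(counts.grid, out, dict(counts.dropped))
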