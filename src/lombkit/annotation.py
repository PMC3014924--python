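"""Positional-zone classification of bins and LOMB-to-nearest-gene association.

Each bin midpoint is placed in exactly one of six zones relative to the gene
models: Upstream >1 kb, Upstream <=1 kb, Gene Body, Downstream <=1 kb,
Downstream >1 kb, and Distant.  Zone precedence resolves bins near multiple
genes deterministically: gene body beats a proximal upstream window, which
beats a proximal downstream window; remaining bins are assigned by their
globally nearest anchor (TSS -> upstream side, polyA -> downstream side)
when that anchor lies within ``distant_cutoff``, and are Distant otherwise.

Independently of the zone, every bin reports its globally nearest
(gene, anchor) pair and the midpoint-to-anchor distance; ties are broken by
lexicographically smallest gene id, then TSS before polyA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinGrid
from .genome_io import GeneModel
from .lomb_calling import LombSet

DEFAULT_WINDOW = 1000
DEFAULT_DISTANT_CUTOFF = 10_000

ZONES = (
    "UpstreamGt1kb",
    "UpstreamLe1kb",
    "GeneBody",
    "DownstreamLe1kb",
    "DownstreamGt1kb",
    "Distant",
)

_CHUNK = 4096


@dataclass
class GeneLombSummary:
    """Per-gene LOMB tallies and the derived gene sets.

    ``upstream_set``/``downstream_set`` are genes with at least one LOMB in
    their <=1 kb upstream/downstream zone; ``any_set`` is genes with any
    associated LOMB; ``none_set`` is the complement within the supplied gene
    universe.  A gene may belong to both directional sets.
    """

    per_gene: pd.DataFrame
    upstream_set: set[str]
    downstream_set: set[str]
    any_set: set[str]
    none_set: set[str]

    @property
    def overlap(self) -> set[str]:
        return self.upstream_set & self.downstream_set


def _gene_arrays(genes: list[GeneModel], chrom: str):
    sub = sorted((g for g in genes if g.chromosome == chrom), key=lambda g: g.gene_id)
    start = np.array([g.start for g in sub], dtype=np.int64)
    end = np.array([g.end for g in sub], dtype=np.int64)
    plus = np.array([g.strand == "+" for g in sub], dtype=bool)
    tss = np.where(plus, start, end - 1)
    polya = np.where(plus, end - 1, start)
    ids = np.array([g.gene_id for g in sub], dtype=object)
    # anchors interleaved per gene, tss first, genes in id order -> argmin on
    # the distance row respects the (gene_id, tss-before-polyA) tie-break
    anchor_pos = np.empty(2 * len(sub), dtype=np.int64)
    anchor_pos[0::2] = tss
    anchor_pos[1::2] = polya
    return ids, start, end, plus, tss, polya, anchor_pos


def classify_midpoints(chrom: str, midpoints: np.ndarray, genes: list[GeneModel],
                       window: int = DEFAULT_WINDOW,
                       distant_cutoff: int = DEFAULT_DISTANT_CUTOFF) -> pd.DataFrame:
    """Vectorized zone + nearest-anchor classification of midpoints on one
    chromosome.  Returns columns zone, nearest_gene, nearest_anchor, distance.
    """
    midpoints = np.asarray(midpoints, dtype=np.int64)
    n = len(midpoints)
    zone = np.full(n, "Distant", dtype=object)
    nearest_gene = np.full(n, "", dtype=object)
    nearest_anchor = np.full(n, "", dtype=object)
    distance = np.full(n, -1, dtype=np.int64)

    ids, start, end, plus, tss, polya, anchor_pos = _gene_arrays(genes, chrom)
    if not len(ids):
        return pd.DataFrame({"zone": zone, "nearest_gene": nearest_gene,
                             "nearest_anchor": nearest_anchor, "distance": distance})

    for lo in range(0, n, _CHUNK):
        mid = midpoints[lo:lo + _CHUNK, None]
        body = ((mid >= start) & (mid < end)).any(axis=1)
        d_tss = np.where(plus, tss - mid, mid - tss)       # >0 means strand-upstream
        d_pa = np.where(plus, mid - polya, polya - mid)    # >0 means strand-downstream
        up_le = ((d_tss > 0) & (d_tss <= window)).any(axis=1)
        dn_le = ((d_pa > 0) & (d_pa <= window)).any(axis=1)

        dist = np.abs(mid - anchor_pos)
        k = dist.argmin(axis=1)
        rows = np.arange(len(k))
        ndist = dist[rows, k]
        is_tss = (k % 2) == 0

        z = np.where(ndist <= distant_cutoff,
                     np.where(is_tss, "UpstreamGt1kb", "DownstreamGt1kb"),
                     "Distant").astype(object)
        z[dn_le] = "DownstreamLe1kb"
        z[up_le] = "UpstreamLe1kb"
        z[body] = "GeneBody"

        sl = slice(lo, lo + len(k))
        zone[sl] = z
        nearest_gene[sl] = ids[k // 2]
        nearest_anchor[sl] = np.where(is_tss, "tss", "polyA")
        distance[sl] = ndist

    return pd.DataFrame({"zone": zone, "nearest_gene": nearest_gene,
                         "nearest_anchor": nearest_anchor, "distance": distance})


def classify_bin(chrom: str, midpoint: int, genes: list[GeneModel],
                 window: int = DEFAULT_WINDOW,
                 distant_cutoff: int = DEFAULT_DISTANT_CUTOFF) -> dict:
    """Classify a single bin midpoint (scalar convenience wrapper)."""
    df = classify_midpoints(chrom, np.array([midpoint]), genes, window, distant_cutoff)
    return df.iloc[0].to_dict()


def annotate_bins(grid: BinGrid, genes: list[GeneModel],
                  window: int = DEFAULT_WINDOW,
                  distant_cutoff: int = DEFAULT_DISTANT_CUTOFF,
                  mask: np.ndarray | None = None) -> pd.DataFrame:
    """Annotate grid bins (by default the euchromatic full-width set) with
    zone and nearest gene.  Returns a frame indexed by bin ordinal with
    columns chrom, start, end, zone, nearest_gene, nearest_anchor, distance.
    """
    if mask is None:
        mask = grid.euchromatic & ~grid.partial
    idx = np.flatnonzero(mask)
    names = grid.chrom_names
    mids = grid.midpoints
    parts = []
    for chrom in [c for c, _ in grid.chromosomes]:
        sel = idx[names[idx] == chrom]
        if not len(sel):
            continue
        df = classify_midpoints(chrom, mids[sel], genes, window, distant_cutoff)
        df.insert(0, "chrom", chrom)
        df.insert(1, "start", grid.start[sel])
        df.insert(2, "end", grid.end[sel])
        df.index = sel
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end", "zone",
                                     "nearest_gene", "nearest_anchor", "distance"])
    return pd.concat(parts).sort_index()


def zone_counts(annotations: pd.DataFrame) -> pd.Series:
    """Bin counts per zone, in canonical zone order."""
    return annotations["zone"].value_counts().reindex(ZONES, fill_value=0)


def associate_lombs(lombs: LombSet, annotations: pd.DataFrame,
                    genes: list[GeneModel],
                    include_distant: bool = False) -> GeneLombSummary:
    """Associate every LOMB with its nearest gene and build the directional
    gene sets.

    A LOMB counts toward a gene only via its own zone: <=1 kb upstream LOMBs
    fill ``upstream_set``, <=1 kb downstream LOMBs fill ``downstream_set``;
    gene-body and >1 kb LOMBs contribute to the gene's total (hence
    ``any_set``) but not to the directional sets.  Distant LOMBs are excluded
    from any_set unless ``include_distant``.
    """
    missing = np.setdiff1d(lombs.lomb_bins, annotations.index.to_numpy())
    if len(missing):
        raise ValueError(f"{len(missing)} LOMB bins lack annotations")
    ann = annotations.loc[lombs.lomb_bins]
    counted = ann if include_distant else ann[ann["zone"] != "Distant"]

    per_gene = (
        counted.assign(n=1)
        .pivot_table(index="nearest_gene", columns="zone", values="n",
                     aggfunc="sum", fill_value=0)
        .reindex(columns=list(ZONES), fill_value=0)
    )
    per_gene.columns.name = None
    per_gene.index.name = "gene_id"
    total = per_gene.sum(axis=1)
    per_gene = per_gene.rename(columns={
        "UpstreamLe1kb": "upstream_lombs",
        "DownstreamLe1kb": "downstream_lombs",
        "GeneBody": "body_lombs",
    })
    per_gene["total_lombs"] = total
    per_gene = per_gene[["upstream_lombs", "downstream_lombs", "body_lombs",
                         "total_lombs"]]

    upstream = set(per_gene.index[per_gene["upstream_lombs"] > 0])
    downstream = set(per_gene.index[per_gene["downstream_lombs"] > 0])
    any_set = set(per_gene.index[per_gene["total_lombs"] > 0])
    universe = {g.gene_id for g in genes}
    return GeneLombSummary(per_gene, upstream, downstream, any_set,
                           universe - any_set)
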