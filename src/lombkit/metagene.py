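"""Strand-oriented metagene profiles around TSS/polyA anchors, with
expression-defined gene classes.

A metagene profile averages, over a gene set, the binned tag count at fixed
offsets from an anchor (TSS or polyA).  Offsets are strand-oriented:
positive offsets point in the direction of transcription.  The count at an
offset is read from the fixed-width bin containing the position (no
interpolation); positions beyond chromosome ends are skipped for that gene.

Expression classes follow a fold/CV rule: genes whose mutant/wild-type
abundance changed at least ``fold``-fold (default 2.5) and whose coefficient
of variance passes ``cv_max`` (default 100%) are classed up or down; genes
failing the CV filter belong to no class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinCounts
from .genome_io import GeneModel

log = logging.getLogger(__name__)

DEFAULT_FLANK = 2000
DEFAULT_STEP = 50
DEFAULT_FOLD = 2.5
DEFAULT_CV_MAX = 100.0


@dataclass
class MetageneProfile:
    """Mean tag count per offset per sample around one anchor type.

    ``n_genes`` is the size of the gene set profiled; ``n_at_offset`` counts
    the genes actually contributing at each offset (genes whose flank runs
    off a chromosome end contribute to fewer offsets).
    """

    anchor: str
    offsets: np.ndarray
    means: dict[str, np.ndarray]
    n_genes: int
    n_at_offset: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, m in self.means.items():
            for o, v, c in zip(self.offsets, m, self.n_at_offset):
                rows.append((self.anchor, int(o), sample, v, int(c)))
        return pd.DataFrame(rows, columns=["anchor", "offset", "sample",
                                           "mean", "n_genes"])


@dataclass
class ExpressionClasses:
    """Disjoint up/down/unchanged gene sets from a fold + CV filter."""

    up_set: set[str]
    down_set: set[str]
    unchanged_set: set[str]
    fold: float
    cv_max: float


def classify_expression(table: pd.DataFrame, fold: float = DEFAULT_FOLD,
                        cv_max: float = DEFAULT_CV_MAX) -> ExpressionClasses:
    """Split genes by mutant/wild-type fold change.

    ``fold_change`` > ``fold`` -> up_set (upregulated in the mutant);
    ``fold_change`` < 1/``fold`` -> down_set; otherwise unchanged.  Genes
    with CV >= ``cv_max`` (percent) are assigned to no class.  Strict
    inequalities throughout.  When the table has no ``cv`` column the CV
    filter is skipped with a warning.
    """
    if fold <= 1:
        raise ValueError("fold cutoff must exceed 1")
    fc = table["fold_change"].astype(float)
    if (fc <= 0).any():
        raise ValueError("non-positive fold change in expression table")
    if "cv" in table.columns:
        ok = table["cv"].astype(float) < cv_max
    else:
        log.warning("expression table has no cv column; CV filter skipped")
        ok = pd.Series(True, index=table.index)
    gid = table["gene_id"].astype(str)
    up = set(gid[ok & (fc > fold)])
    down = set(gid[ok & (fc < 1.0 / fold)])
    unchanged = set(gid[ok]) - up - down
    return ExpressionClasses(up, down, unchanged, fold, cv_max)


def metagene_profile(counts: BinCounts, genes: list[GeneModel], anchor: str,
                     flank: int = DEFAULT_FLANK, step: int = DEFAULT_STEP,
                     samples: list[str] | None = None) -> MetageneProfile:
    """Average per-sample bin counts at strand-oriented offsets
    -flank..+flank (step ``step``) around each gene's TSS or polyA."""
    if anchor not in ("tss", "polyA"):
        raise ValueError("anchor must be 'tss' or 'polyA'")
    if not genes:
        raise ValueError("empty gene subset")
    if flank % step:
        raise ValueError("flank must be a multiple of step")
    samples = samples or counts.samples
    grid = counts.grid
    offsets = np.arange(-flank, flank + step, step, dtype=np.int64)
    lengths = dict(grid.chromosomes)

    sums = {s: np.zeros(len(offsets)) for s in samples}
    n_at = np.zeros(len(offsets), dtype=np.int64)
    for g in genes:
        a = g.tss if anchor == "tss" else g.polyA
        sign = 1 if g.strand == "+" else -1
        pos = a + sign * offsets
        ok = (pos >= 0) & (pos < lengths[g.chromosome])
        if not ok.any():
            continue
        idx = grid.offsets[g.chromosome] + pos[ok] // grid.width
        n_at[ok] += 1
        for s in samples:
            sums[s][ok] += counts.counts[s][idx]

    if n_at.max() == 0:
        raise ValueError("no gene contributes any in-bounds offset")
    with np.errstate(invalid="ignore"):
        means = {s: np.where(n_at > 0, v / np.maximum(n_at, 1), np.nan)
                 for s, v in sums.items()}
    return MetageneProfile(anchor, offsets, means, len(genes), n_at)
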