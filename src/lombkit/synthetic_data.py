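"""Seeded two-condition ChIP-seq tag simulator with recorded ground truth.

The generator emulates the structure of a genome-wide repressive-mark
(H3K9me2-like) profile in a wild-type and a methyltransferase-mutant
condition:

* a heterochromatin-like block at the distal end of each chromosome with
  ``het_multiplier``-fold elevated intensity in *both* conditions (the
  negative control: planted losses never touch heterochromatin);
* coverage dips at gene TSS and polyA anchors (``dip_depth``), realized at
  bin resolution: bins wholly inside ``anchor ± dip_halfwidth`` are
  attenuated, so the dip is bookkept exactly on the bin grid;
* condition-specific loss of methylation: a designated subset of genes
  receives whole-bin-aligned planted regions — preferentially within 1 kb
  of the 5'/3' gene ends — where the mutant intensity is divided by
  ``lom_fold``;
* Poisson tag noise per bin per condition at ``base_intensity`` expected
  tags per full-width euchromatic bin (a gamma-Poisson over-dispersed mode
  is available via ``dispersion``); tags are fixed-length reads with
  midpoints uniform within their bin.

Identical configurations (including the seed) yield identical tag sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ZONES
from .binning import BinCounts, BinGrid, make_bins
from .genome_io import GeneModel, GenomeModel, TagSet, make_tagset, write_intervals
from .lomb_calling import LombSet

ZONE_CHOICES = ("upstream", "downstream", "body")


@dataclass
class SimConfig:
    """Simulation parameters.  The defaults define the standard benchmark:
    two 9-Mb chromosomes tiled into 300-bp bins, one-sixth heterochromatin
    (50,000 euchromatic bins), mean depth 20 tags/bin, 100 target genes with
    two planted bins each (200 planted bins) at 8-fold mutant loss."""

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 9_000_000
    bin_width: int = 300
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (2000, 8000)
    gene_min_gap: int = 2500
    het_fraction: float = 1.0 / 6.0
    base_intensity: float = 20.0
    het_multiplier: float = 3.0
    dip_depth: float = 0.5
    dip_halfwidth: int = 300
    n_target_genes: int = 100
    lom_fold: float = 8.0
    lom_region_bins: int = 2
    lom_zone_bias: tuple[float, float, float] = (0.35, 0.45, 0.20)
    zone_plan: list[str] | None = None
    read_length: int = 36
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.dip_depth <= 1:
            raise ValueError("dip_depth must be in (0, 1]")
        if self.lom_fold < 1:
            raise ValueError("lom_fold must be >= 1")
        if not 0 <= self.het_fraction < 1:
            raise ValueError("het_fraction must be in [0, 1)")
        if any(p < 0 or p > 1 for p in self.lom_zone_bias) or sum(self.lom_zone_bias) <= 0:
            raise ValueError("zone bias must be probabilities with positive sum")


def benchmark_config(seed: int = 1) -> SimConfig:
    """The fixed recovery benchmark: 50,000 euchromatic bins, depth 20,
    8-fold loss, 200 planted bins (0.4% of bins)."""
    return SimConfig(seed=seed)


def asymmetry_config(seed: int = 1) -> SimConfig:
    """A genome-scale-signal configuration: ~5% of euchromatic bins carry
    planted loss, the regime in which the fitted SD is inflated by the
    signal itself and the negative tail of the ratio distribution nearly
    empties — the positive/negative call asymmetry seen in real data."""
    return SimConfig(
        seed=seed, n_genes=1300, gene_length_range=(1500, 4000),
        gene_min_gap=2200, n_target_genes=1250, lom_region_bins=2,
    )


@dataclass
class SimTruth:
    """Ground truth of one simulation: planted regions, planted bin
    ordinals, and the per-bin expected intensities per condition."""

    planted_regions: pd.DataFrame
    planted_bins: np.ndarray
    wt_intensity: np.ndarray
    mt_intensity: np.ndarray


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeModel
    genes: list[GeneModel]
    grid: BinGrid
    tags_wt: TagSet
    tags_mt: TagSet
    truth: SimTruth


def _place_genes(cfg: SimConfig, rng: np.random.Generator,
                 euch_len: int) -> list[GeneModel]:
    margin = 3000
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(cfg.n_chromosomes):
        n = int(per_chrom[ci])
        lengths = rng.integers(cfg.gene_length_range[0],
                               cfg.gene_length_range[1] + 1, n)
        strands = rng.choice(np.array(["+", "-"], dtype=object), n)
        needed = 2 * margin + int(lengths.sum()) + n * cfg.gene_min_gap
        slack = euch_len - needed
        if slack < 0:
            raise ValueError("infeasible placement: genes too dense for chromosome")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        cursor = margin + int(extra[0])
        for j in range(n):
            start = cursor
            end = start + int(lengths[j])
            genes.append(GeneModel(f"g{gid:05d}", f"chr{ci + 1}", str(strands[j]),
                                   start, end))
            cursor = end + cfg.gene_min_gap + int(extra[j + 1])
            gid += 1
    return genes


def _window_bins(grid: BinGrid, chrom: str, lo: float, hi: float,
                 ref: int) -> np.ndarray:
    """Bin ordinals whose midpoints lie in [lo, hi], nearest to ``ref`` first."""
    off = grid.offsets[chrom]
    first = off + max(0, int(lo) // grid.width)
    last = off + int(hi) // grid.width + 1
    cand = np.arange(first, min(last + 1, grid.n_bins))
    mids = grid.midpoints[cand]
    cand = cand[(mids >= lo) & (mids <= hi)]
    return cand[np.argsort(np.abs(grid.midpoints[cand] - ref), kind="stable")]


def _plant_bins(cfg: SimConfig, grid: BinGrid, gene: GeneModel,
                zone: str) -> np.ndarray:
    """Whole-bin-aligned planted region for one gene and zone; bins are
    selected by the same midpoint convention the annotation module uses."""
    w = 1000
    if zone == "upstream":
        if gene.strand == "+":
            cand = _window_bins(grid, gene.chromosome, gene.tss - w, gene.tss - 1, gene.tss)
        else:
            cand = _window_bins(grid, gene.chromosome, gene.tss + 1, gene.tss + w, gene.tss)
    elif zone == "downstream":
        if gene.strand == "+":
            cand = _window_bins(grid, gene.chromosome, gene.polyA + 1, gene.polyA + w, gene.polyA)
        else:
            cand = _window_bins(grid, gene.chromosome, gene.polyA - w, gene.polyA - 1, gene.polyA)
    elif zone == "body":
        cand = _window_bins(grid, gene.chromosome, gene.start, gene.end - 1,
                            (gene.start + gene.end) // 2)
    else:
        raise ValueError(f"unknown zone {zone!r}")
    cand = cand[grid.euchromatic[cand] & ~grid.partial[cand]]
    if not len(cand):
        raise ValueError(f"infeasible placement: no bins for {gene.gene_id}/{zone}")
    return np.sort(cand[: cfg.lom_region_bins])


def _sample_tags(rng: np.random.Generator, grid: BinGrid, intensity: np.ndarray,
                 sample_id: str, read_length: int, dispersion: float) -> TagSet:
    lam = intensity
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=len(lam))
    n = rng.poisson(lam)
    total = int(n.sum())
    bin_start = np.repeat(grid.start, n)
    bin_len = np.repeat(grid.end - grid.start, n)
    mids = bin_start + (rng.random(total) * bin_len).astype(np.int64)
    chrom = np.repeat(grid.chrom_names, n)
    lens_per_bin = np.array([l for _, l in grid.chromosomes])[grid.chrom_index]
    lmax = np.repeat(lens_per_bin, n)
    start = np.clip(mids - read_length // 2, 0, lmax - read_length)
    strand = rng.choice(np.array(["+", "-"], dtype=object), total)
    return make_tagset(sample_id, chrom, start, start + read_length, strand)


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: genome + mask, genes, per-bin intensities per
    condition, planted loss regions, and Poisson-realized tag sets."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    het_len = int(round(cfg.chrom_length * cfg.het_fraction
                        / cfg.bin_width)) * cfg.bin_width
    euch_len = cfg.chrom_length - het_len
    chroms = [(f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chromosomes)]
    mask = pd.DataFrame(
        [(name, euch_len, cfg.chrom_length) for name, _ in chroms],
        columns=["chrom", "start", "end"],
    ) if het_len else pd.DataFrame(columns=["chrom", "start", "end"])
    genome = GenomeModel(chroms, mask)
    grid = make_bins(genome, cfg.bin_width)

    genes = _place_genes(cfg, rng, euch_len)

    # wild-type intensity: base, het elevation, anchor dips
    widths = (grid.end - grid.start) / cfg.bin_width
    wt = cfg.base_intensity * widths
    wt[~grid.euchromatic] *= cfg.het_multiplier
    for g in genes:
        for a in (g.tss, g.polyA):
            off = grid.offsets[g.chromosome]
            b0 = off + max(0, (a - cfg.dip_halfwidth)) // grid.width
            for b in range(int(b0), min(grid.n_bins, int(b0) + 3)):
                if (grid.chrom_index[b] == grid.chrom_index[off]
                        and grid.start[b] >= a - cfg.dip_halfwidth
                        and grid.end[b] <= a + cfg.dip_halfwidth + 1):
                    wt[b] *= cfg.dip_depth

    # planted mutant loss
    if cfg.n_target_genes > len(genes):
        raise ValueError("infeasible placement: more target genes than genes")
    t_idx = np.sort(rng.choice(len(genes), cfg.n_target_genes, replace=False))
    if cfg.zone_plan is not None:
        if len(cfg.zone_plan) != cfg.n_target_genes:
            raise ValueError("zone_plan length must equal n_target_genes")
        plans = list(cfg.zone_plan)
    else:
        p = np.asarray(cfg.lom_zone_bias, dtype=float)
        plans = list(rng.choice(np.array(ZONE_CHOICES, dtype=object),
                                cfg.n_target_genes, p=p / p.sum()))

    mt = wt.copy()
    planted: list[int] = []
    regions = []
    for gi, plan in zip(t_idx, plans):
        g = genes[gi]
        zones = ("upstream", "downstream") if plan == "both" else (plan,)
        for zone in zones:
            bins = _plant_bins(cfg, grid, g, zone)
            mt[bins] /= cfg.lom_fold
            planted.extend(int(b) for b in bins)
            regions.append((g.gene_id, zone, g.chromosome,
                            int(grid.start[bins[0]]), int(grid.end[bins[-1]]),
                            cfg.lom_fold))
    planted_bins = np.unique(np.array(planted, dtype=np.int64))
    truth = SimTruth(
        pd.DataFrame(regions, columns=["gene_id", "zone", "chrom", "start",
                                       "end", "lom_fold"]),
        planted_bins, wt, mt,
    )

    tags_wt = _sample_tags(rng, grid, wt, "wt", cfg.read_length, cfg.dispersion)
    tags_mt = _sample_tags(rng, grid, mt, "mt", cfg.read_length, cfg.dispersion)
    return SimResult(cfg, genome, genes, grid, tags_wt, tags_mt, truth)


def expected_counts(result: SimResult) -> BinCounts:
    """Noise-free per-bin expected intensities as a BinCounts (for tests)."""
    return BinCounts(result.grid, {"wt": result.truth.wt_intensity.copy(),
                                   "mt": result.truth.mt_intensity.copy()})


def truth_compare(called: LombSet, truth: SimTruth, grid: BinGrid,
                  annotations: pd.DataFrame | None = None) -> dict:
    """Recovery metrics of a call set against the planted truth.

    sensitivity = fraction of planted bins called; false-positive rate =
    fraction of unplanted euchromatic full-width bins called.  With bin
    annotations supplied, adds a planted-zone x annotated-zone confusion
    table.
    """
    if len(truth.wt_intensity) != grid.n_bins:
        raise ValueError("truth and grid disagree on bin count")
    planted = set(truth.planted_bins.tolist())
    called_set = set(np.asarray(called.lomb_bins).tolist())
    n_planted = len(planted)
    euch = set(np.flatnonzero(grid.euchromatic & ~grid.partial).tolist())
    negatives = euch - planted
    tp = len(called_set & planted)
    fp = len(called_set & negatives)
    out = {
        "sensitivity": tp / n_planted if n_planted else float("nan"),
        "false_positive_rate": fp / len(negatives) if negatives else float("nan"),
        "n_planted": n_planted,
        "n_called": len(called_set),
    }
    if annotations is not None:
        zone_map = {}
        for row in truth.planted_regions.itertuples():
            off = grid.offsets[row.chrom]
            for b in range(off + row.start // grid.width,
                           off + (row.end - 1) // grid.width + 1):
                zone_map[b] = row.zone
        conf = pd.DataFrame(0, index=list(ZONE_CHOICES), columns=list(ZONES))
        for b, z in zone_map.items():
            if b in annotations.index:
                conf.loc[z, annotations.loc[b, "zone"]] += 1
        out["zone_confusion"] = conf
    return out


def write_bundle(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the simulation as the exact input formats the pipeline reads:
    chrom.sizes, gene TSV, heterochromatin mask BED, per-condition tag BED,
    and a planted-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in {
        "chrom_sizes": "genome.chrom.sizes", "genes": "genes.tsv",
        "mask": "heterochromatin.bed", "wt": "tags_wt.bed",
        "mt": "tags_mt.bed", "truth": "truth.tsv"}.items()}
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in result.genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    pd.DataFrame(
        [(g.gene_id, g.chromosome, g.strand, g.start, g.end) for g in result.genes],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    ).to_csv(paths["genes"], sep="\t", index=False)
    write_intervals(result.genome.het_mask, paths["mask"], "bed")
    for key, ts in (("wt", result.tags_wt), ("mt", result.tags_mt)):
        df = ts.tags.sort_values(["chrom", "start"], kind="stable")
        df = df.assign(name=".", score=0)[["chrom", "start", "end", "name",
                                           "score", "strand"]]
        df.to_csv(paths[key], sep="\t", header=False, index=False)
    result.truth.planted_regions.to_csv(paths["truth"], sep="\t", index=False)
    return paths
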