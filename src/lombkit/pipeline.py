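"""End-to-end orchestration: count -> equalize -> ratios -> LOMB call ->
annotate -> enrich -> metagene, with file outputs and a machine-readable
summary.

Defaults reproduce the standard analysis parameters: 300-bp bins, 2-SD
calling threshold, 1-kb proximal windows, 2.5-fold expression cutoff.  The
core analysis is fully deterministic; all randomness lives in the simulator
and the optional subsampling equalization mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import annotation as ann_mod
from . import binning, genome_io, lomb_calling, metagene
from .enrichment import zone_enrichment

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All pipeline inputs and parameters."""

    chrom_sizes: str
    genes: str
    wt_tags: str
    mt_tags: str
    outdir: str
    mask: str | None = None
    expression: str | None = None
    gene_format: str = "auto"
    bin_width: int = binning.DEFAULT_BIN_WIDTH
    pseudocount: float = lomb_calling.DEFAULT_PSEUDOCOUNT
    k: float = lomb_calling.DEFAULT_K
    window: int = ann_mod.DEFAULT_WINDOW
    distant_cutoff: int = ann_mod.DEFAULT_DISTANT_CUTOFF
    metagene_flank: int = metagene.DEFAULT_FLANK
    metagene_step: int = metagene.DEFAULT_STEP
    expression_fold: float = metagene.DEFAULT_FOLD
    cv_max: float = metagene.DEFAULT_CV_MAX
    seed: int = 0
    deduplicate: bool = True

    def params(self) -> dict:
        # outdir excluded: identical inputs must give byte-identical outputs
        # regardless of where they are written
        return {k: v for k, v in self.__dict__.items() if k != "outdir"}


@dataclass
class RunResult:
    summary: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _checksum(path: str) -> str:
    try:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()[:12]
    except OSError:
        return "unreadable"  # the owning stage reports the real error


def _header(cfg: RunConfig) -> list[str]:
    lines = [f"lombkit {__version__}"]
    lines += [f"param {k}={v}" for k, v in sorted(cfg.params().items())]
    for name in ("chrom_sizes", "genes", "wt_tags", "mt_tags", "mask", "expression"):
        path = getattr(cfg, name)
        if path:
            lines.append(f"input {name} sha256:{_checksum(path)}")
    return lines


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every analysis stage in order; any failure aborts with the
    stage name.  Outputs land in ``config.outdir``; the returned summary is
    also written as JSON."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {"parameters": {k: str(v) for k, v in cfg.params().items()}}
    header = _header(cfg)

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t = stage("load")
        genome = genome_io.read_chrom_sizes(cfg.chrom_sizes)
        if cfg.mask:
            genome = genome_io.read_mask(cfg.mask, genome)
        tags_wt = genome_io.read_tags(cfg.wt_tags, genome, "wt", cfg.deduplicate)
        tags_mt = genome_io.read_tags(cfg.mt_tags, genome, "mt", cfg.deduplicate)
        log.info("load done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage load failed: {e}") from e

    try:
        t = stage("count")
        grid = binning.make_bins(genome, cfg.bin_width)
        counts = binning.count_samples([tags_wt, tags_mt], grid)
        counts = binning.equalize_libraries(counts)
        path = outdir / "bin_counts.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            counts.to_frame().to_csv(fh, sep="\t", index=False)
        outputs["bin_counts"] = path
        summary["library_totals"] = {s: counts.total(s) for s in counts.samples}
        log.info("count done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage count failed: {e}") from e

    try:
        t = stage("call-lombs")
        ratios = lomb_calling.compute_log_ratios(counts, "wt", "mt", cfg.pseudocount)
        lombs = lomb_calling.call_lombs(ratios, cfg.k)
        summary.update(lomb_calling.summarize(ratios, lombs))

        bed = pd.DataFrame({
            "chrom": grid.chrom_names[lombs.lomb_bins],
            "start": grid.start[lombs.lomb_bins],
            "end": grid.end[lombs.lomb_bins],
            "name": "LOMB",
            # BED score: log2 ratio x100 truncated to integer
            "score": (ratios.log2_ratio[lombs.lomb_bins] * 100).astype(int),
        }).sort_values(["chrom", "start"], kind="stable")
        outputs["lomb_bed"] = outdir / "lombs.bed"
        genome_io.write_intervals(bed, outputs["lomb_bed"], "bed", header)

        regions = lomb_calling.merge_adjacent(lombs, grid)
        outputs["lomb_regions"] = outdir / "lomb_regions.bed"
        genome_io.write_intervals(
            regions.rename(columns={"n_bins": "score"}).assign(name="LOM_region")[
                ["chrom", "start", "end", "name", "score"]],
            outputs["lomb_regions"], "bed", header)

        retained = ratios.retained
        track = pd.DataFrame({
            "chrom": grid.chrom_names[retained],
            "start": grid.start[retained],
            "end": grid.end[retained],
            "value": ratios.log2_ratio[retained].round(4),
        })
        outputs["ratio_track"] = outdir / "log2_ratio.bedgraph"
        genome_io.write_intervals(track, outputs["ratio_track"], "bedgraph", header)
        log.info("call-lombs done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage call-lombs failed: {e}") from e

    try:
        t = stage("annotate")
        genes = genome_io.read_genes(cfg.genes, genome, cfg.gene_format)
        annotations = ann_mod.annotate_bins(grid, genes, cfg.window, cfg.distant_cutoff)
        path = outdir / "bin_annotation.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            annotations.to_csv(fh, sep="\t", index_label="bin")
        outputs["bin_annotation"] = path

        assoc = ann_mod.associate_lombs(lombs, annotations, genes)
        path = outdir / "gene_lomb_summary.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            assoc.per_gene.to_csv(fh, sep="\t")
        outputs["gene_lomb_summary"] = path
        for name, ids in (("upstream", assoc.upstream_set),
                          ("downstream", assoc.downstream_set),
                          ("any", assoc.any_set), ("none", assoc.none_set)):
            p = outdir / f"genes_{name}_lomb.txt"
            genome_io.write_gene_set(ids, p)
            outputs[f"genes_{name}"] = p
        summary["gene_sets"] = {
            "any_lomb": len(assoc.any_set),
            "upstream_lomb": len(assoc.upstream_set),
            "downstream_lomb": len(assoc.downstream_set),
            "updown_overlap": len(assoc.overlap),
            "no_lomb": len(assoc.none_set),
        }
        log.info("annotate done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage annotate failed: {e}") from e

    try:
        t = stage("enrich")
        all_counts = ann_mod.zone_counts(annotations)
        lomb_counts = ann_mod.zone_counts(annotations.loc[lombs.lomb_bins])
        enr = zone_enrichment(lomb_counts.to_numpy(), all_counts.to_numpy())
        path = outdir / "zone_enrichment.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write(f"#chi2={enr.chi2:.4g} chi2_p={enr.chi2_p:.4g} df={enr.chi2_df}\n")
            enr.table.to_csv(fh, sep="\t", index=False)
        outputs["zone_enrichment"] = path
        summary["zone_enrichment"] = {
            r.zone: {"fold": r.fold, "p_bonferroni": r.p_bonferroni}
            for r in enr.table.itertuples()
        }
        summary["zone_chi2_p"] = enr.chi2_p
        log.info("enrich done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage enrich failed: {e}") from e

    try:
        t = stage("metagene")
        gene_classes: dict[str, list] = {"all": genes}
        if cfg.expression:
            expr = genome_io.read_expression(cfg.expression)
            classes = metagene.classify_expression(expr, cfg.expression_fold, cfg.cv_max)
            by_id = {g.gene_id: g for g in genes}
            gene_classes["up"] = [by_id[g] for g in classes.up_set if g in by_id]
            gene_classes["down"] = [by_id[g] for g in classes.down_set if g in by_id]
        frames = []
        for cls, subset in gene_classes.items():
            if not subset:
                continue
            for anchor in ("tss", "polyA"):
                prof = metagene.metagene_profile(counts, subset, anchor,
                                                 cfg.metagene_flank, cfg.metagene_step)
                frames.append(prof.to_frame().assign(gene_class=cls))
        path = outdir / "metagene_profiles.tsv"
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write("#counts=equalized\n")
            pd.concat(frames).to_csv(fh, sep="\t", index=False)
        outputs["metagene"] = path
        log.info("metagene done in %.1fs", time.perf_counter() - t)
    except Exception as e:
        raise StageError(f"stage metagene failed: {e}") from e

    outputs["summary"] = outdir / "summary.json"
    with open(outputs["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return RunResult(summary, outputs)
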