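import numpy as np
import pandas as pd
import pytest

from lombkit.annotation import (
    ZONES, annotate_bins, associate_lombs, classify_bin, classify_midpoints,
    zone_counts,
)
from lombkit.binning import count_samples, equalize_libraries
from lombkit.genome_io import GeneModel
from lombkit.lomb_calling import LombSet, call_lombs, compute_log_ratios
from lombkit.synthetic_data import expected_counts, simulate

from conftest import random_gene_models, small_config
from oracles import brute_classify


class TestClassifyBin:
    """Worked examples around a + strand gene spanning [5000, 8000)."""

    def test_proximal_upstream(self, plus_gene):
        c = classify_bin("chrA", 4500, [plus_gene])
        assert c["zone"] == "UpstreamLe1kb"
        assert (c["nearest_gene"], c["nearest_anchor"], c["distance"]) == ("g1", "tss", 500)

    def test_gene_body(self, plus_gene):
        assert classify_bin("chrA", 6000, [plus_gene])["zone"] == "GeneBody"

    def test_proximal_downstream(self, plus_gene):
        c = classify_bin("chrA", 8400, [plus_gene])
        assert c["zone"] == "DownstreamLe1kb"
        assert (c["nearest_anchor"], c["distance"]) == ("polyA", 401)

    def test_distal_zones_and_distant(self, plus_gene):
        assert classify_bin("chrA", 3000, [plus_gene])["zone"] == "UpstreamGt1kb"
        assert classify_bin("chrA", 12000, [plus_gene])["zone"] == "DownstreamGt1kb"
        assert classify_bin("chrA", 30000, [plus_gene])["zone"] == "Distant"

    def test_minus_strand_orientation(self):
        g = GeneModel("g1", "chrA", "-", 5000, 8000)  # tss=7999, polyA=5000
        assert classify_bin("chrA", 8400, [g])["zone"] == "UpstreamLe1kb"
        assert classify_bin("chrA", 4600, [g])["zone"] == "DownstreamLe1kb"

    def test_window_boundary_inclusive(self, plus_gene):
        assert classify_bin("chrA", 4000, [plus_gene])["zone"] == "UpstreamLe1kb"
        assert classify_bin("chrA", 3999, [plus_gene])["zone"] == "UpstreamGt1kb"

    def test_no_genes_everything_distant(self):
        df = classify_midpoints("chrA", np.array([100, 5000]), [])
        assert (df["zone"] == "Distant").all()


class TestBruteForceAgreement:
    def test_matches_exhaustive_scan_small(self):
        rng = np.random.default_rng(5)
        genes = random_gene_models(rng, 12)
        mids = rng.integers(0, 100_000, 300)
        got = classify_midpoints("chr1", mids, genes)
        for i, mid in enumerate(mids):
            want = brute_classify(int(mid), genes)
            assert got.iloc[i].to_dict() == want, f"midpoint {mid}"

    def test_tie_break_smallest_gene_then_tss(self):
        # two genes with anchors equidistant from the midpoint
        a = GeneModel("ga", "chr1", "+", 1000, 2000)   # tss 1000
        b = GeneModel("gb", "chr1", "-", 400, 601)     # tss 600, polyA 400
        c = classify_bin("chr1", 800, [b, a])
        assert (c["nearest_gene"], c["nearest_anchor"]) == ("ga", "tss")


class TestZonePartition:
    def test_zone_counts_cover_retained_bins(self, benchmark_sim, benchmark_annotation):
        grid = benchmark_sim.grid
        retained = int((grid.euchromatic & ~grid.partial).sum())
        assert int(zone_counts(benchmark_annotation).sum()) == retained

    def test_mirror_invariance(self):
        """Reversing coordinates and flipping strands leaves zone labels fixed."""
        L = 20_000
        genes = [GeneModel("g1", "c", "+", 5000, 8000),
                 GeneModel("g2", "c", "-", 11000, 14000)]
        mirror = [GeneModel(g.gene_id, "c", "-" if g.strand == "+" else "+",
                            L - g.end, L - g.start) for g in genes]
        mids = np.arange(100, L, 37)
        fwd = classify_midpoints("c", mids, genes)
        rev = classify_midpoints("c", L - 1 - mids, mirror)
        assert fwd["zone"].tolist() == rev["zone"].tolist()


class TestAssociateLombs:
    def _lombs(self, bins):
        return LombSet(2.0, 0.0, 1.0, np.array(bins, dtype=np.int64),
                       np.array([], dtype=np.int64))

    def test_single_upstream_lomb(self, benchmark_sim, benchmark_annotation):
        ann = benchmark_annotation
        up = ann.index[ann["zone"] == "UpstreamLe1kb"][:1]
        summ = associate_lombs(self._lombs(list(up)), ann, benchmark_sim.genes)
        gene = ann.loc[up[0], "nearest_gene"]
        assert summ.upstream_set == {gene}
        assert summ.downstream_set == set()
        assert summ.any_set == {gene}
        assert gene not in summ.none_set

    def test_unannotated_lomb_rejected(self, benchmark_sim, benchmark_annotation):
        bad = np.flatnonzero(~benchmark_sim.grid.euchromatic)[:1]
        with pytest.raises(ValueError, match="lack annotations"):
            associate_lombs(self._lombs(list(bad)), benchmark_annotation,
                            benchmark_sim.genes)

    def test_designed_up_down_overlap_recovery(self):
        """LOMs planted at 40 genes (20 upstream, 15 downstream, 5 both)
        are recovered as directional sets of 25/20 with overlap 5."""
        plan = ["upstream"] * 20 + ["downstream"] * 15 + ["both"] * 5
        cfg = small_config(seed=11, n_genes=60, chrom_length=900_000,
                           n_target_genes=40, zone_plan=plan,
                           lom_fold=16.0, base_intensity=30.0)
        res = simulate(cfg)
        counts = expected_counts(res)  # noise-free intensities
        lombs = call_lombs(compute_log_ratios(counts, "wt", "mt"))
        assert set(lombs.lomb_bins.tolist()) == set(res.truth.planted_bins.tolist())
        ann = annotate_bins(res.grid, res.genes)
        summ = associate_lombs(lombs, ann, res.genes)
        assert len(summ.upstream_set) == 25
        assert len(summ.downstream_set) == 20
        assert len(summ.overlap) == 5
        assert len(summ.any_set) == 40
        assert len(summ.none_set) == 20

    def test_per_gene_totals_match_lomb_count(self, benchmark_sim,
                                              benchmark_annotation,
                                              benchmark_lombs):
        _, lombs = benchmark_lombs
        summ = associate_lombs(lombs, benchmark_annotation, benchmark_sim.genes,
                               include_distant=True)
        assert summ.per_gene["total_lombs"].sum() == lombs.n_lomb
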