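import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lombkit.binning import BinCounts, make_bins
from lombkit.genome_io import GenomeModel
from lombkit.lomb_calling import (
    call_lombs, compute_log_ratios, fit_distribution, merge_adjacent,
    threshold_fold,
)


def counts_from(wt, mt, length=None):
    wt = np.asarray(wt, float)
    mt = np.asarray(mt, float)
    length = length or 300 * len(wt)
    grid = make_bins(GenomeModel([("c", length)]), 300)
    return BinCounts(grid, {"wt": wt, "mt": mt})


class TestLogRatios:
    def test_fourfold_loss_without_pseudocount(self):
        r = compute_log_ratios(counts_from([4.0], [1.0]), "wt", "mt", 0.0)
        assert r.log2_ratio[0] == pytest.approx(2.0)

    def test_equal_counts_give_zero(self):
        for c in (0.0, 1.0, 5.0):
            r = compute_log_ratios(counts_from([7.0], [7.0]), "wt", "mt", c)
            assert r.log2_ratio[0] == pytest.approx(0.0)

    def test_zero_handling(self):
        r = compute_log_ratios(counts_from([0, 3, 0], [0, 0, 2]), "wt", "mt", 0.0)
        # both-zero always excluded; with c=0, any zero excluded
        assert r.retained.tolist() == [False, False, False]
        r1 = compute_log_ratios(counts_from([0, 3, 0], [0, 0, 2]), "wt", "mt", 1.0)
        assert r1.retained.tolist() == [False, True, True]
        assert np.isfinite(r1.retained_ratios).all()

    def test_partial_and_het_bins_not_retained(self):
        grid = make_bins(GenomeModel(
            [("c", 950)],
            pd.DataFrame({"chrom": ["c"], "start": [0], "end": [300]})), 300)
        counts = BinCounts(grid, {"wt": np.ones(4), "mt": np.ones(4)})
        r = compute_log_ratios(counts, "wt", "mt")
        assert r.retained.tolist() == [False, True, True, False]

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            compute_log_ratios(counts_from([1], [1]), "wt", "nope")


class TestFitDistribution:
    def test_constant_ratios(self):
        r = compute_log_ratios(counts_from([4.0] * 5, [1.0] * 5), "wt", "mt", 0.0)
        mu, sigma = fit_distribution(r)
        assert (mu, sigma) == (2.0, 0.0)

    def test_two_point_case(self):
        # ratios {-1, +1}: mean 0, population SD 1
        r = compute_log_ratios(counts_from([1.0, 2.0], [2.0, 1.0]), "wt", "mt", 0.0)
        assert fit_distribution(r) == (0.0, 1.0)

    def test_recovers_normal_moments(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(0.2, 1.0, 10_000)
        wt = 2.0 ** draws
        r = compute_log_ratios(counts_from(wt, np.ones_like(wt)), "wt", "mt", 0.0)
        mu, sigma = fit_distribution(r)
        assert mu == pytest.approx(0.2, abs=0.05)
        assert sigma == pytest.approx(1.0, abs=0.05)

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            fit_distribution(compute_log_ratios(counts_from([1.0], [1.0]), "wt", "mt"))


class TestCallLombs:
    def test_threshold_fold_arithmetic(self):
        assert threshold_fold(0.2, 1.0, 2) == pytest.approx(2 ** 2.2)
        assert round(threshold_fold(0.2, 1.0, 2), 1) == 4.6
        assert threshold_fold(0.0, 1.0, 2) == pytest.approx(4.0)

    def test_brute_force_threshold(self):
        wt = 2.0 ** np.array([0, 0, 0, 0, 5.0])
        r = compute_log_ratios(counts_from(wt, np.ones(5)), "wt", "mt", 0.0)
        lombs = call_lombs(r, k=1)
        mu, sd = r.retained_ratios.mean(), r.retained_ratios.std()
        expect = np.flatnonzero(r.retained_ratios > mu + sd)
        assert lombs.lomb_bins.tolist() == expect.tolist() == [4]

    def test_degenerate_distribution_rejected(self):
        r = compute_log_ratios(counts_from([2.0] * 4, [1.0] * 4), "wt", "mt", 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            call_lombs(r)

    def test_ties_at_threshold_not_called(self):
        # ratios {-1,-1,1,1}: mu=0 sd=1; k=1 thresholds at +-1; strict ">"
        wt = 2.0 ** np.array([-1.0, -1, 1, 1])
        r = compute_log_ratios(counts_from(wt, np.ones(4)), "wt", "mt", 0.0)
        lombs = call_lombs(r, k=1)
        assert lombs.n_lomb == 0 and lombs.n_gain == 0

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=8, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_swap_antisymmetry(self, pairs):
        """Swapping wt and mt negates every ratio and exchanges call sides."""
        wt = np.array([p[0] for p in pairs], float)
        mt = np.array([p[1] for p in pairs], float)
        fwd = compute_log_ratios(counts_from(wt, mt), "wt", "mt", 1.0)
        rev = compute_log_ratios(counts_from(mt, wt), "wt", "mt", 1.0)
        assert np.array_equal(fwd.retained, rev.retained)
        np.testing.assert_allclose(fwd.retained_ratios, -rev.retained_ratios,
                                   atol=1e-12)
        if fwd.n_retained >= 2 and fwd.retained_ratios.std() > 0:
            a, b = call_lombs(fwd), call_lombs(rev)
            assert a.lomb_bins.tolist() == b.gain_bins.tolist()
            assert a.gain_bins.tolist() == b.lomb_bins.tolist()

    def test_increasing_k_never_adds_lombs(self, benchmark_counts):
        r = compute_log_ratios(benchmark_counts, "wt", "mt")
        prev = None
        for k in (1.0, 1.5, 2.0, 2.5, 3.0):
            called = set(call_lombs(r, k).lomb_bins.tolist())
            if prev is not None:
                assert called <= prev
            prev = called


class TestMergeAdjacent:
    def _lombs(self, bins):
        class L:
            lomb_bins = np.array(bins, dtype=np.int64)
        return L()

    def test_adjacent_bins_merge(self):
        grid = make_bins(GenomeModel([("c", 1500)]), 300)
        out = merge_adjacent(self._lombs([1, 2]), grid)
        assert out.to_records(index=False).tolist() == [("c", 300, 900, 2)]

    def test_gap_splits_regions(self):
        grid = make_bins(GenomeModel([("c", 1500)]), 300)
        out = merge_adjacent(self._lombs([1, 3]), grid)
        assert len(out) == 2

    def test_chromosome_boundary_never_merges(self):
        grid = make_bins(GenomeModel([("a", 600), ("b", 600)]), 300)
        # bins 1 and 2 are consecutive ordinals but on different chromosomes
        out = merge_adjacent(self._lombs([1, 2]), grid)
        assert len(out) == 2

    def test_empty_set(self):
        grid = make_bins(GenomeModel([("c", 900)]), 300)
        assert len(merge_adjacent(self._lombs([]), grid)) == 0
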