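# Methods

## The analysis model

`lombkit` implements a two-condition differential analysis for a broad
repressive chromatin mark (H3K9me2-type) profiled by ChIP-seq in a
wild-type and a methyltransferase-mutant strain, one library per condition.
The method is deliberately simple — a pure threshold rule on binned tag
ratios — and every step is deterministic:

1. **Binning.** The genome is tiled into fixed 300-bp bins. A bin is
   *euchromatic* unless its midpoint falls inside the supplied
   heterochromatin mask. Trailing sub-width bins at chromosome ends are kept
   (so whole-chromosome tracks can be rendered) but flagged partial and
   excluded from all ratio statistics, because their counts are
   length-confounded.
2. **Counting.** Each mapped tag is assigned to the single bin containing
   its interval midpoint, `floor((start+end)/2)`. Midpoint assignment is
   symmetric and gives exact count conservation; 5'-end assignment can be
   emulated by passing single-base tags.
3. **Library equalization.** Every sample's count vector is multiplied by
   `min_total / its_total`, so all library totals equal the smallest one and
   the smallest library is untouched. Scaling is deterministic and produces
   real-valued counts; a seeded multivariate-hypergeometric subsampling mode
   (`subsample_libraries`) is available when integer counts are required.
4. **Ratios.** For every retained bin (euchromatic, full-width, `wt+mt>0`)
   the log2 methylation ratio is

       r_b = log2((wt_b + c) / (mt_b + c)),   c = 1 by default.

   The pseudocount keeps ratios finite at low coverage without discarding
   bins; with `c = 0`, zero-count bins are excluded instead. The pseudocount
   is applied symmetrically, so swapping the two samples negates every
   ratio exactly.
5. **Calling.** The ratio distribution is summarized by its arithmetic mean
   `mu` and *population* standard deviation `sigma` over the retained bins
   — no trimming and no robust estimator, matching a direct reading of the
   ratio histogram. Loss-of-methylation bins (LOMBs) are bins with
   `r_b > mu + k*sigma` (default `k = 2`); gain-side bins use the mirrored
   threshold. Inequalities are strict: a bin exactly at the threshold is
   not called. The threshold is also reported as a fold change,
   `2^(mu + k*sigma)`; for the canonical published moments (mean 0.2, SD 1)
   this is `2^2.2 = 4.59 ≈ 4.6`.
6. **Annotation.** Each bin midpoint is placed in one of six positional
   zones: Upstream >1 kb, Upstream ≤1 kb, Gene Body, Downstream ≤1 kb,
   Downstream >1 kb, Distant. Precedence for bins near several genes:
   gene body, then ≤1 kb strand-upstream of a TSS, then ≤1 kb
   strand-downstream of a polyA; remaining bins take the side of their
   globally nearest anchor when it lies within `distant_cutoff` (10 kb by
   default — the published zoning never defines "Distant", so the cutoff is
   configurable and recorded in output headers). "Within 1 kb" is
   inclusive (`distance <= 1000`). Independently of the zone, every bin
   reports its globally nearest (gene, anchor) pair; distance ties go to
   the lexicographically smallest gene id, then TSS before polyA.
7. **Gene association.** Every LOMB is credited to its nearest gene, via
   its own zone only: ≤1 kb upstream LOMBs define the upstream gene set,
   ≤1 kb downstream LOMBs the downstream set; body and >1 kb LOMBs count
   toward the gene's total (hence the any-LOMB set) but not the directional
   sets. Distant LOMBs are excluded from the any-LOMB set by default
   (`include_distant` reverses this). A gene may carry both upstream and
   downstream LOMBs; the overlap is reported.
8. **Enrichment.** Zone enrichment is an exact upper-tail hypergeometric
   test of the LOMB zone counts against the all-bins background,
   Bonferroni-corrected over the six zones; fold is
   `(observed/total LOMBs)/(background/total bins)`. A global chi-squared
   statistic compares the whole LOMB zone distribution against the
   background scaled to the LOMB total (5 df). Depletion can be tested with
   the lower tail (`lower=True`). Gene-set overlaps use the same tail
   probability on gene counts; batteries of set tests are corrected by
   Benjamini–Hochberg. The tail is accumulated in log space
   (`logsumexp` over `hypergeom.logpmf`), which stays exact at tails around
   1e-300 where a survival-function complement would underflow.
9. **Metagene profiles.** Strand-oriented average bin counts at offsets
   −2000..+2000 bp (step 50) around TSS or polyA anchors, read from the bin
   containing each position — no interpolation, because the data structure
   is the bin grid itself. Profiles default to equalized counts: that is the
   only scale on which the two conditions are comparable, and the choice is
   recorded in the output metadata. Expression classes use a fold/CV rule:
   mutant/wild-type fold > 2.5 (up) or < 1/2.5 (down), genes with
   coefficient of variance ≥ 100% assigned to no class; when the table has
   replicate columns, fold is `mean(mt)/mean(wt)` and the CV is computed on
   per-replicate mt/wt ratios, and when only a fold column exists the CV
   filter is skipped with a warning.

### Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| bin width | 300 | bp | ~2 nucleosomes; the resolution of the original analysis |
| pseudocount `c` | 1 | tags | keeps ratios finite; negligible at depth ≈ 20 |
| `k` | 2 | SD | the published calling stringency |
| proximal window | 1000 | bp | promoter/terminator scale in a compact genome |
| `distant_cutoff` | 10000 | bp | separates ">1 kb" zones from "Distant" |
| metagene flank/step | 2000 / 50 | bp | covers both proximal windows with sub-bin sampling |
| expression fold / CV | 2.5 / 100% | — | the published microarray filter |

## The synthetic-data generator

The generator (`synthetic_data`) emulates the *structure* of the real data
so that every pipeline stage has known truth:

* **Genome**: `n_chromosomes` × `chrom_length`, with a contiguous
  heterochromatin-like block at the distal end of each chromosome
  (`het_fraction`, bin-aligned) — the analogue of the assembled
  heterochromatic arm extensions.
* **Baseline signal**: Poisson tag counts per bin per condition,
  `base_intensity` expected tags per full euchromatic bin; heterochromatic
  bins get `het_multiplier`× intensity *in both conditions* — the negative
  control that the caller must leave alone. An optional gamma-Poisson
  mode (`dispersion > 0`) produces over-dispersed counts.
* **Gene-end dips**: bins lying wholly inside `anchor ± dip_halfwidth` of a
  TSS or polyA are attenuated by `dip_depth` in both conditions. Dips are
  realized at whole-bin resolution, the same bookkeeping rule as planted
  regions: a sub-bin positional dip sampled through 300-bp bins would
  produce a flat expectation plateau across ±150 bp and make "where is the
  minimum" undecidable, whereas the whole-bin rule gives a strict expected
  minimum at offset 0 and an exact min/shoulder ratio of `dip_depth`.
* **Planted loss**: `n_target_genes` genes receive whole-bin-aligned
  regions of `lom_region_bins` bins in which the *mutant* intensity is
  divided by `lom_fold`. Placement is ≤1 kb upstream of the TSS, ≤1 kb
  downstream of the polyA, or mid-gene-body, drawn from `lom_zone_bias`
  (or dictated per gene by `zone_plan`, including "both"). Genes are placed
  with ≥`gene_min_gap` spacing so planted zones cannot collide with
  neighboring genes' proximal windows.
* **Tags**: 36-bp reads (the read length of the platform era;
  configurable), midpoints uniform within the bin, random strand. A fixed
  seed gives byte-identical output.

### The two signal regimes

Two named configurations are provided, and the distinction is scientific,
not cosmetic:

* `benchmark_config()` — **sparse signal** (200 planted bins among 50,000,
  0.4%): the fitted SD is noise-dominated, so the mean+2SD rule behaves
  like a fixed-FPR detector. This is the regime for measuring *recovery*:
  at depth 20 and 8-fold loss, sensitivity is ≥ 0.9 (measured 1.00 at
  seed 1) and the false-positive rate sits at the one-sided normal 2-SD
  tail (~2%) on *both* sides — positive and negative call counts are
  nearly symmetric, necessarily.
* `asymmetry_config()` — **genome-scale signal** (2,500 planted bins, 5%,
  the loss fraction the real data shows): the planted signal itself
  inflates the fitted SD (≈ 0.48 → 0.75 here), the threshold moves far
  beyond the noise quantiles, and the negative tail nearly empties. This
  reproduces the strong positive/negative call asymmetry of the real
  analysis (≈ 20:1 across seeds) and the signal-inflated mean (≈ +0.1).
  No symmetric-noise simulation can show this asymmetry in the sparse
  regime — the two configurations exist because the two claims (recovery
  rate, asymmetry) are only meaningful in different regimes.

### What passing tests do not show

The generator draws independent Poisson (optionally gamma-Poisson) counts
per bin: it has no mappability or GC structure, no fragment-length
smearing across bin boundaries, no input-chromatin background, no
copy-number variation, and exactly one interval per gene. Recovery rates
measured here therefore bound what the threshold rule can do under its own
assumptions, not under real library artifacts. Equalization by scaling
also cannot repair composition bias between libraries — with genuinely
asymmetric loss, scaling to the smaller library slightly shifts the ratio
mean, which is visible in the simulation (mean ≈ +0.1 under 5% loss) and
in the published mean (+0.2).

## Numerical choices and degenerate inputs

* Population SD (`ddof=0`); immaterial at genome scale, fixed for
  determinism.
* Strict inequalities at both calling thresholds; ties are not called.
* `sigma = 0` (all ratios identical) is an error, not an empty call set.
* Bins with `wt+mt = 0` are never retained; with `c = 0`, bins with any
  zero are dropped from retention.
* Nearest-anchor ties: lexicographically smallest gene id, then TSS before
  polyA — matched exactly by the brute-force oracle in the tests.
* Equalization requires ≥ 2 samples with positive totals.
* `write_intervals` refuses unsorted input rather than silently sorting,
  so that round-trips are bit-exact.

## Problem sizes used in tests

The fixed benchmark runs two 9-Mb chromosomes (60,000 bins, 50,000
euchromatic) at depth 20 — about 1.6 M tags per condition — and completes
in a few seconds; unit tests use a 0.6-Mb single-chromosome configuration.
The zone-enrichment recovery test uses a 6-Mb genome with 400 genes so
that a 3× downstream placement rate for 2,000 simulated LOMBs remains
feasible without replacement. These sizes were chosen as the smallest at
which the statistical assertions have comfortable margins.

## Known limitations

* One library per condition: no replicate variance model, no per-bin
  p-values, no FDR over bins — the method is a pure SD-threshold rule by
  design.
* One interval per gene id: callers must pre-collapse isoforms; the polyA
  anchor is the 3'-most annotated base, the only proxy derivable from gene
  models.
* The published genome-wide totals (384,944 bins, 19,258 LOMBs, the
  5,136/1,229/1,712/255 gene sets) derive from the original mapped
  libraries and annotation release and are not recomputable from desk-scale
  inputs; the package verifies the arithmetic that connects them (threshold
  fold, genome fraction, overlap probability) and reproduces the
  qualitative structure on simulations.
* Plot rendering is not included; all profile and enrichment outputs are
  TSV designed for standard plotting tools.
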