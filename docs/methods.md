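# Methods

This note documents the models and procedures implemented in `exitkit`,
the defaults they ship with, the design choices that were genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## Tile-based differential methylation

CpG records carry per-site methylated/unmethylated read counts (0-based
positions internally; the bismark-coverage dialect's 1-based inclusive
coordinates are converted at the I/O boundary). The analysis chain is:

1. **Per-sample filtering.** Sites with coverage below `min_depth`
   (default 5) are removed; then sites strictly above the (1 − f)
   empirical coverage quantile (default f = 0.001, linear-interpolation
   quantile) are removed per sample — the usual guard against
   PCR-amplified outlier sites. Filtering is order-independent.
2. **Common sites.** Only CpGs present in every sample are retained, so
   all downstream quantities share one site universe.
3. **Tiling.** Non-overlapping tiles anchored at multiples of `tile_size`
   (default 400 bp) from coordinate 0; tiles with fewer than `min_cpgs`
   (default 3) common CpGs are dropped. Tile methylation is
   coverage-weighted — 100·Σmeth/(Σmeth+Σunmeth) — not the mean of site
   percentages. Anchored, non-overlapping tiling keeps tiles disjoint so
   the per-tile tests are independent for multiple-testing correction;
   a sliding variant would correlate adjacent tests.
4. **Differential calling.** Replicate counts are pooled within each
   condition/timepoint group, and each tile's 2×2 pooled table gets a
   two-sided Fisher exact test with Benjamini–Hochberg q-values over all
   tested tiles. A tile is a DMR iff |Δmethylation| > 20 percentage
   points *and* q < 0.05 (both strict). Pooled exact testing is the
   standard default when no replicate-variance model is fitted; it is
   exact at low coverage and fully reproducible. The two-sided p sums all
   hypergeometric pmf terms ≤ the observed term (relative tie tolerance
   1e-7, the convention of R's `fisher.test`).
5. **Temporal accounting.** For a t1→t2 comparison, gain = hyper at t2,
   loss = hypo, percentages are relative to the tiles tested in that
   comparison. `maintained_acquisition` takes the gain DMRs of an early
   interval and flags each `lost` when the later timepoint drops more
   than the DMR threshold below the acquired level.

## Genomic regions

Region classes are BED interval sets. Enhancers are extended ±1 kb and
merged. A tile belongs to a class when it overlaps ≥ 1 bp; multi-class
overlaps resolve by a configurable precedence (default CGI > canyon >
HCP > LCP > enhancer > TE > exon > intron > other); tiles touching
nothing are `other`. Promoters split into HCP/LCP at CpG
observed/expected ratio 0.29, computed as (N_CpG · L)/(N_C · N_G) with N
bases excluded from counts and length; the boundary is strict (ratio
exactly at threshold → LCP) and exposed as a parameter. Metagene
profiles length-normalize gene bodies into 40 bins with 20 fixed-width
bins per 10 kb flank (bin counts are parameters; nothing in the data
dictates them), reverse minus-strand genes so bins run 5′→3′, weight by
coverage, and report empty bins as missing rather than zero.

## Bipartite motif scanning and enrichment

A hit is an ordered pair of half-site matches on the same strand with
0 ≤ gap ≤ max_gap, where the gap runs from the end of the first site to
the start of the second — half-sites may be adjacent but never overlap.
When the two half-site motifs differ, both orders are each counted once.
Minus-strand hits are found by scanning the reverse complement and are
reported in plus-strand coordinates. Two presets ship because the
source protocols themselves differ: `methods` (YACCTG twice, gap ≤ 40)
and `results-fig2d` (CACCTG + CACCT, gap ≤ 45); the default is
`methods`, and exposing both was preferred to silently resolving the
discrepancy. Enrichment binarizes promoters (≥ 1 hit) — a 2×2 exact
test needs per-promoter presence, though raw hit counts are also
reported — and tests each DEG partition one-sided against the
genome-wide promoter background, which includes the foreground genes
(a disjoint-background option exists). Odds ratios use a Haldane 0.5
correction when a cell is zero.

## Transcriptome utilities

TPM divides counts by gene length and rescales each sample to 1e6.
Gene filtering applies three steps in order: drop short-noncoding
biotypes; keep genes with ≥ 5 TPM in ≥ 3 samples (both boundaries
inclusive); drop the 20% least variable genes, with variability the SD
of log2(TPM+1) across samples and boundary ties broken by
(variability, gene id). The variability cutoff is *fitted* on first use
and stored on the `GeneFilter` object, so the fitted filter is
idempotent — re-applying it to its own output keeps every gene. A
re-fit on filtered output would recompute the 20% quantile and trim
again, which is rarely what a caller means; fitting once is the
transformer semantics used across sklearn-style APIs.

DEG status is up iff log2FC > 1 and p < 0.01 (strict; raw p as printed
in the consumed table, with a q-based option), down symmetrically.
pi-values are −log10(q)·log2FC with q = 0 clamped to the smallest
positive q observed, preserving ranks without infinities; log2 is used
for the fold-change factor, matching the scale of the consumed table.
Persistence between timepoints is plain set algebra on status series,
with switchers and dropouts reported so the t1 DEG set is partitioned
exactly. Clustering uses 1 − Spearman (average ranks on ties) with
UPGMA linkage; leaf order is deterministic (the subtree containing the
smaller minimum input index goes left at every merge).

The differential-expression model itself is consumed, not implemented:
the pipeline expects a per-gene (log2FC, p, q) table from an external
tool. For closed-loop testing, `synthetic.nb_two_group_test` provides a
deliberately simple stand-in: median-of-ratios size factors (robust to
asymmetric differential expression, where total-count scaling drags
null genes past the fold-change threshold) followed by a per-gene Welch
t-test on log2(normalized+1) with BH correction.

## qPCR panel processing

Assays are kept when detected in ≥ 50% of samples (inclusive; wells
below a quality floor count as undetected first). Sample outliers are
flagged on an aggregation score — the mean over assays of the detected
flag weighted by well quality — using median − k·MAD with k = 3 and the
MAD scaled by 1.4826 (the normal-consistency factor; the unscaled MAD
would make k = 3 an aggressive ≈2σ rule). Quantile normalization
replaces each sample's sorted observed values by cross-sample rank
means, averaging tied groups; samples with unequal observed counts are
aligned by linear interpolation of the reference distribution on [0,1].
Missing wells are then imputed with the assay mean over the sample's
replicate group; wells missing across the whole group are placed at the
LOD afterwards. The LOD is the 75% quantile (type-7) of all normalized
Ct pooled over the matrix, plus a constant of 10 cycles ("overall"
argues for pooling; a per-assay variant exists behind a flag);
log2 expression = LOD − Ct, absolute expression = 2^log2.

Quantile normalization is rank-based, so a planted Ct shift is
reconstructed at the resolution of the local assay density; on a
96-assay panel the per-panel fold-change estimate carries a few tenths
of a log2 unit of rank-resolution noise but is unbiased, which is what
the validation measures (seed-averaged recovery within ±0.5 log2).

## Peak proximity enrichment

Peaks anchor at their midpoint (or declared summit offset); each is
assigned to the region with the nearest midpoint on its chromosome,
ties to the lower coordinate, signed by genome coordinates (regions are
unstranded). Distances are histogrammed within ±10 kb in 500 bp bins.
Significance comes from a permutation null — peak midpoints re-placed
uniformly per chromosome, preserving per-chromosome counts — with a
2.5/97.5 percentile envelope and an enrichment ratio over the null mean
floored at one pseudo-count. The original analysis plotted enrichment
without stating a null; the permutation background makes the claim
testable. GC- or coverage-matched nulls are out of scope.

## Synthetic data: what it emulates, and what it does not

The generators define the validation conditions; they are pure
functions of (parameters, seed) and export all planted truth.

- **Methylome.** Per-tile baselines come from a bimodal Beta mixture
  (hypo mode Beta(1,9), hyper mode Beta(9,1), 55% hypo), reproducing the
  bimodal per-site 5%-bin histograms of real CpG methylomes. Coverage is
  truncated negative binomial (size 4, minimum 1 read, mean `depth_mean`
  = 20 by default) — RRBS-like over-dispersion; only thresholds matter
  downstream. Tiles carry 6–12 CpGs, the density RRBS enrichment
  produces in the CpG-rich fraction it targets. The trajectory encodes
  the studied biology: ~34% of tiles gain 25–40 points of methylation
  after the first timepoint in *both* conditions; the control then holds
  steady, while the perturbed condition loses a planted delta (default
  −30 points, always ≥ threshold + 5 so recovery is well-posed) at the
  final timepoint. Planted loss tiles are members of the gain programme
  — the methylation they lose is the methylation they just acquired —
  which is what makes the acquired-then-lost accounting testable.
- **Counts.** NB(mean = baseline·2^lfc, variance = μ + αμ²) with α =
  0.05 and log-uniform baselines in [200, 2000]; 3 vs 3 replicates by
  default.
- **Ct panels.** Assay levels U(18, 30), sample shifts N(0, 0.5), well
  noise N(0, 0.25), uniform dropout; outlier samples get +6 cycles and
  +0.45 dropout. Planted fold changes subtract cycles from one
  replicate group.
- **Peaks.** Target peaks center on region midpoints with Gaussian
  jitter; background peaks are uniform per chromosome.
- **Motif promoters.** All half-sites are scrubbed from every promoter
  window, then exactly one bipartite pair is written into each selected
  promoter, making the truth exact when promoter windows do not overlap.

Limits: no read-level simulation or bisulfite chemistry, no strand
asymmetry, no chromatin covariates, no GC bias in peaks or coverage,
independence between sites and between genes. Passing the recovery
tests shows the pipelines are correct and calibrated under these
conditions; it does not certify performance on real data with
correlated errors, batch structure or mapping artifacts.

## Numerical choices

- Quantiles are linear-interpolation (type-7, the NumPy default)
  everywhere a quantile is taken.
- Exact-test p-values are computed through the hypergeometric
  distribution, vectorized over tiles/tables; validation compares them
  to an independent log-factorial tail-sum enumeration over all 2×2
  tables with margins ≤ 60 (one-sided agreement ≲ 1e-12, two-sided
  ≲ 1e-10).
- Benjamini–Hochberg q-values propagate NaNs (untested entries stay
  untested).
- Degenerate inputs fail loudly: empty inputs warn and return empty;
  zero-variance items, non-partitioning replicate groups, mismatched
  tile universes and unknown labels raise with the offender named.

## Validation problem sizes

The shipped validation uses 2,000-tile methylomes at depth 20 (5 seeds
for recovery, 20 for null calibration), 1,000 scanner sequences of
2 kb, the full ≤ 60-margin table enumeration (~3.6M tables), 20-seed
peak power/calibration runs at 200 permutations, 100-seed outlier
recovery and 15-seed fold-change recovery on 96-assay panels — sizes
chosen so the complete suite exercises every claim in a few minutes on
a single CPU.
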