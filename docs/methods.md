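# Methods

This note documents the statistical procedures implemented in `mplkit`,
the defaults chosen where a design was genuinely open, what the synthetic
generator does and does not emulate, and known limitations.

## Beta values and quality control

A beta value is β = Meth / (Meth + Unmeth + offset) with offset 100 by
default; the offset guards against near-zero total intensity, so β < 1
strictly and β = 0 iff Meth = 0. Matrices are sites-in-rows /
samples-in-columns (the GEO series-matrix convention), missing values are
`NA` on disk and NaN in memory, and genomic coordinates follow the 1-based
Illumina MAPINFO convention. Quality control removes *samples* — never
sites — that contain any value below 0, above 1, or missing; the filter is
idempotent and reports each dropped sample with its reasons. Out-of-range
values are retained at read time precisely so the filter can see them.

## r-beta profiles

Each site's beta values are rounded to two decimals — round-half-to-even,
matching the IEEE/R rounding used when such matrices are produced upstream;
the rule is centralized in `profiles.round_to_grid` so half-up would be a
one-line change — and binned onto the grid 0.00 … 1.00. Proportions are
counts over the number of non-missing values, so they sum to exactly 1
(held as integer counts; `exact_proportions()` exposes the rationals).
Peak finding operates on a centred moving average (window 5 bins) with a
prominence floor of 0.02; both are display-level defaults with no deeper
justification, and the profile is zero-padded one bin beyond the kernel
radius so fully (un)methylated sites still show their boundary peak.
Kernel densities use a Gaussian kernel with Silverman's rule-of-thumb
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated at 512 points on
[−0.05, 1.05]; constant input falls back to bandwidth 0.01 so the single
mode stays visible.

## Plasticity scores

Four spread measures quantify MPL per site: IQR (Q75−Q25, the default
score), Q95−Q5, sample SD (n−1 denominator) and the range (max−min). They
trade sample support against sensitivity: half the data lies outside the
IQR, 10% outside Q95−Q5, and none outside the range, which a single
outlier can carry. Quantiles use linear interpolation of order statistics
(the common type-7 rule); the five-number summary uses Tukey hinges, which
differ from type-7 quartiles for some n, so both are reported and the IQR
is always the type-7 difference. Sites with fewer than two values receive
no score and are counted in the table's metadata. Ranking sorts by
descending score with lexicographic site-ID tie-breaks for determinism.

## Tendency classification

Counts of values in [0, 0.5) and (0.5, 1] are tested against equal
expectation with a 1-df chi-square goodness of fit (no continuity
correction — Yates applies to 2×2 contingency, not 1-df GOF). p ≤ α
(default 0.05) with the excess above 0.5 gives MTS, below gives UTS,
otherwise NTS. Values exactly 0.5 indicate balanced probe signal and
belong to neither interval; they are excluded from both counts, and an
all-0.5 site is NTS with p = 1 by convention (logged). Calls require at
least 4 values. Partially-methylated "dual tendency" is folded into NTS:
both name the nonsignificant case, and genuinely multi-modal sites are
reported separately by the split detector. The mirror transform v → 1−v
swaps MTS ↔ UTS at identical p (n_lower and n_upper exchange), which the
test suite asserts exactly.

## Split methylation

**Clustering.** `pam_1d` minimizes the k-medoids objective (total absolute
deviation of each value to its cluster medoid, medoids being data points).
In one dimension the optimal clusters are contiguous runs of the sorted
values, so the global optimum is found exactly by dynamic programming over
segment boundaries in O(n²k); this replaces the generic BUILD+SWAP local
search, which demonstrably stalls in single-swap local optima on inputs as
small as n = 9, k = 3, while the DP solution provably matches exhaustive
medoid search (asserted against it in the tests). Determinism: stable
sort, earliest-boundary tie-breaks, lower-median medoid per segment.
Distances are raw absolute differences — beta values share a scale, so no
standardisation is applied.

**Homogeneity.** The Duda–Hart statistic is
SS_within(best 2-cluster split) / SS_total, with the 2-partition taken
from `pam_1d(k=2)`; the critical value for dimension p = 1 at level α
(default 0.001) is `1 − 2/(πp) − z_α·sqrt(2(1 − 8/(π²p))/(np))`, and the
site is homogeneous iff the ratio is at least critical. All-identical
input is homogeneous by convention. Two consequences of this formula worth
knowing: the critical value is *negative* for n < ~28, so no site can be
called split below that cohort size; and its slow sqrt(1/n) approach to
the asymptote 1 − 2/π ≈ 0.363 means weak multi-modal structure needs large
cohorts (see limitations).

**k selection.** Heterogeneous sites are clustered for
k = 2 … min(k_max, distinct − 1) (k_max default 10) and the k with the
largest average silhouette width wins, smaller k on ties.

**Stratification.** Each sample's composite label is the tuple of its
cluster indices over the chosen split sites; at most Πk_i groups can
occur, fewer when sites are correlated. Groups are ordered by descending
size and samples by (group, ID), an ordering suitable for heatmaps.

## Differential methylation

Two-sided Mann–Whitney U per shared site (sidedness fixed at two-sided:
neither direction is privileged a priori). Mode `auto` uses the exact null
distribution when both groups have ≤ 25 values and the pooled data has no
ties, otherwise the tie-corrected normal approximation with continuity
correction; both behaviours are exposed directly via `exact` / `normal`.
Missing values are dropped per site per group and the per-site group sizes
recorded. Bonferroni (α/n, and min(1, p·n) per-value) and
Benjamini–Hochberg step-up adjustments are applied across sites; at
genome-wide scale the Bonferroni threshold 0.05/485 512 ≈ 1.03e−7
motivates the common p < 1e−7 significance guideline. The effect size is
the median difference (B − A), with an optional absolute-difference filter
(default off: statistical and biological significance are reported, not
conflated). Tendency inversions between the groups are flagged from the
tendency module when both groups support a call.

## Synthetic generator

Each site draws a per-sample component, then a beta value from a Beta
distribution with shapes (mean·κ, (1−mean)·κ) — mean/concentration
parameterisation, truncated into (1e−6, 1−1e−6) so no bin degenerates.
Kinds: single-component methylated/unmethylated/balanced sites
(κ = 50, per-component sd ≈ 0.05–0.07, the typical array noise scale);
`split_hwe` sites drawing genotypes at Hardy–Weinberg proportions
(p², 2pq, q²) with one mean per genotype; `split_sex` sites keyed to the
sample sheet's Bernoulli(0.5) sex. Split components default to κ = 100 in
the preset corpus so each genotype/sex cluster forms the distinct, narrow
peak this structure produces in real profiles. An optional per-site
condition shift moves the mean for "case" samples, which is how
differential sites are engineered; pooled across conditions such a site is
a genuine 2-component mixture and its truth label says so. Everything is
reproducible from one integer seed.

The **preset corpus** (1000 sites × 200 samples) mixes 60%
methylation-tendency-like, 35% unmethylation-tendency-like, 3% balanced,
1.5% Hardy–Weinberg trimodal (allele frequency 0.5, genotype means
0.04/0.45/0.89) and 0.5% sex-linked bimodal sites (female/male means
0.54/0.82), with 100 control / 100 case samples and 50 differential sites
shifted by +0.3. It is sized to run the full pipeline in well under two
minutes on one CPU.

What the generator does *not* emulate: Infinium I/II probe-type chemistry,
between-study batch effects, cell-type composition mixtures, spatial
correlation between neighbouring CpGs, or detection-p-value noise. Tests
passing on synthetic data therefore validate the statistical machinery
under clean mixture assumptions, not robustness to those artefacts.

## Numerical choices and degenerate inputs

Round-half-to-even at the profile grid; integer counts for exact
proportion sums; Fraction-based assertions in tests. PAM cost ties break
toward the earliest segment boundary; silhouette ties toward smaller k.
Constant sites: homogeneous by convention (SS = 0), zero for every MPL
score, KDE falls back to a fixed narrow bandwidth. Empty inputs raise
typed errors rather than returning sentinels. All randomness flows through
`numpy.random.default_rng(seed)`.

## Known limitations

* **Duda–Hart power at desk scale.** For the Hardy–Weinberg trimodal
  geometry (means 0.04/0.45/0.89, weights 0.25/0.5/0.25) the best
  2-partition leaves SS_within/SS_total ≈ 0.32–0.35, while the α = 0.001
  critical value is 0.229 at n = 200 and only exceeds 0.32 beyond
  n ≈ 2000. Such sites are therefore invisible to the gated detector in
  small cohorts and need thousands of samples — which matches where this
  phenomenon is observed in practice. The benchmark accounts for this:
  cluster-number recovery is asserted corpus-wide, and Hardy–Weinberg
  proportion recovery is asserted by clustering the trimodal sites at the
  known genotype number.
* The ±0.02 proportion-recovery band is only meaningful when the number of
  genotype draws makes it several binomial standard errors wide; the
  acceptance test uses 7500 draws (≈ 4 SE).
* Tendency calls at the minimum n = 4 have little power; strict labels are
  more informative there.
* No batch-effect modelling or correction; analyses assume comparably
  processed inputs, and small significant differences between
  heterogeneous sources should be interpreted with the effect-size filter.
* The exact-0.5 exclusion rule is a convention; with 2-decimal data it
  affects a visible sample fraction only for sites centred tightly on 0.5.
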