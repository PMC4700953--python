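# Methods

## Study design the package models

Two commercial egg-layer populations (white-egg WL and brown-egg BL, 25
diploid hens each, individually sequenced and jointly genotyped) are
contrasted with three meat-type broiler populations sequenced as DNA pools
(BR1–BR3), which yield per-site read counts but no genotypes or haplotypes.
All statistics are computed on the alternate-allele orientation of the
reference genome for every population, so "elevated frequency" always means
the same physical allele — the premise of a parallel-selection argument.

## Site filters

* Biallelic SNPs only; multi-allelic records and indels are dropped and
  counted (no decomposition).
* Phred-scaled site quality ≥ 20 (≈ 99 % call accuracy).
* Total read depth within mean ± 2 SD of the depth distribution, computed
  once over the whole filtered-input set (population SD, ddof = 0, inclusive
  band, single pass — the band is not re-estimated after filtering). A single
  dataset-wide band is used rather than per-chromosome bands.
* Pooled sites with fewer than `min_pool_depth = 4` reads in a pool are
  *masked* for that pool (frequency undefined) but kept in the site frame so
  tables stay aligned. Frequencies estimated from fewer than 4 reads are too
  noisy to window-average; masking rather than dropping preserves the common
  site set.
* Cross-table alignment keeps (chrom, pos)-matching sites; a table whose
  ref/alt is swapped relative to the first table is flipped (dosages
  complemented, counts exchanged, logged); irreconcilable alleles drop the
  site everywhere. Coordinates are 1-based in files, 0-based half-open
  internally, and regions are reported 1-based inclusive.

## Window frame

Overlapping windows of `window_size` = 40 kb advancing in `step` = 5 kb,
anchored at coordinate 0 of each chromosome; trailing partial windows are
discarded so every window statistic averages an equal span (windows =
⌊(L − W)/S⌋ + 1). A window's value is the arithmetic mean of the defined
site values inside it; windows with fewer than `min_snps_per_window` = 5
defined sites are missing. At 107 bp mean spacing a 40 kb window holds
~370 SNPs, so the default only suppresses pathologically sparse windows.

## Parallel-fixation screen

Decision statistic: the across-population **minimum** of the window-mean
alternate-allele frequencies (all-populations rule: min ≥ τ ⟺ every
population ≥ τ). τ defaults to 0.85 and the comparison is inclusive, so a
population sitting exactly at 0.85 passes. Windows missing in any population
are never flagged — a parallel claim may not rest on an absent population,
which is also why the group mean over pools is missing wherever any single
pool is masked. Flagged windows adjacent on the grid (start difference =
step; a configurable gap tolerance, default 0, can bridge unflagged windows)
merge into regions; a region reports the mean and the max window AF per
population over its members.

## Divergence screen

Per-site Fst between the layer group and the broiler group uses the Weir &
Cockerham (1984) two-population estimator θ̂ = a/(a + b + c) computed from
(frequency, sample size) pairs. Because pooled genotypes are unobserved, the
within-population heterozygosity term is the HWE expectation 2p(1 − p); the
same convention is applied to the layers for symmetry (a config switch
allows genotype-pooling of layers instead of averaging the two layer
tracks). The haplotype-equivalent sample size of a pool is its read depth
capped at `max_pool_n` = 50 (2 × 25 birds), so deep pools do not overstate
precision. Negative per-site estimates — expected wherever the groups do not
differ — are retained in window means; only the final report offers a
display column clamped at 0.

Windows are flagged at the empirical top quantile (default top 1 %) using a
nearest-rank rule: the threshold t is the k-th largest window value with
k = ⌈(1 − q)·N⌉, and the flag set {v ≥ t} is inclusive, so ties enlarge it.
The empirical percentile of an observation is self-inclusive,
P = #{v ≥ obs}/N, with minimum 1/N. A merged region's P is the minimum over
its member windows (pairing naturally with the reported maximum Fst; the
per-region alternative of ranking region summaries against each other is a
defensible variant not taken here). The genome-wide Fst is the multi-locus
WC84 combination Σa / Σ(a + b + c) — the estimator's own prescription for
combining loci; the plain mean of per-site ratios is biased downward
(≈ 0.135 at a true F of 0.18 in this design) because the expectation of a
ratio is not the ratio of expectations. Chromosome-class stratification
defaults to the chicken karyotype: GGA1–5 macro, GGA6–10 intermediate
(excluded from the micro/macro contrast), GGA11+ micro; the map is
user-overridable and echoed in run metadata.

A Hudson-style estimator with finite-sample correction,
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) over
D = p₁(1−p₂) + p₂(1−p₁), is exposed as a config-selectable cross-check. At
equal sample sizes the two estimators nearly coincide (max |Δ| < 0.01 on a
random grid); under strongly unequal sizes they diverge by design, which is
why the cross-check is run at equal n.

## Haplotype statistics

EHH for a core allele is the probability that two random carriers are
identical at every site between the core and a query position, computed by
partition refinement outward from the core; it is 1 at the core and
non-increasing. A curve stops at the first value below the truncation cutoff
(0.05), at the chromosome edge, or at an inter-site gap above `max_gap`
(200 kb). iHH integrates the curve (trapezoid over physical distance, both
directions summed, including the first below-cutoff point); a core whose
curve is censored by an edge or a gap before truncating is missing, as its
integral would be biased low. iHS_raw = ln(iHH_a/iHH_d) for cores with
derived-allele frequency and its complement ≥ 0.05, then standardized to
mean 0/SD 1 (population SD) within 20 equal-width derived-frequency bins;
bins with fewer than two scores, or zero spread, leave their members
missing (the latter with a warning). Physical distance stands in for
genetic distance: no chicken genetic map ships with the package and the
generator has no recombination-rate variation. Unphased input is a hard
error — silently phasing would corrupt the statistic. The scan track is the
window mean of |iHS| (absolute value first, then averaged).

## Synthetic-data generator

The generator emulates the sampling design, not chicken demography:

* SNP positions: exponential inter-site gaps (mean `mean_spacing` = 107 bp,
  floored at 1 bp), on one synthetic chromosome.
* Ancestral frequencies: Uniform(0.05, 0.95) — symmetric, avoiding rare
  alleles that pooled sequencing under-represents anyway.
* Population frequencies: Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F)
  per population with F = `baseline_fst` = 0.18, drawn independently per
  population and per pool. F is the one differentiation parameter the study
  design fixes, which is why BN was chosen over a forward simulation.
* Layer haplotypes: site-independent Bernoulli draws given the population
  frequency (phased; ancestral allele = reference allele in emitted VCF, so
  polarization is known). Pool counts: depth ~ Poisson(`pool_depth` = 30)
  per site per pool — a realistic pool-seq coverage, not stated by the
  original design — and alt reads ~ Binomial(depth, pool frequency).
* Sweeps: inside the tract where the hitchhiking excess exceeds 1 % of the
  center excess, the target frequency is p(d) = p_bg + (p_sweep − p_bg)e^(−d/L).
  Without a core haplotype, target-population alleles are redrawn
  independently at p(d). With one, ⌈p_sweep·n⌉ carrier chromosomes share a
  single per-site allele draw with probability w(d) chosen so the expected
  frequency still equals p(d) (clipped to [0,1]); carriers are therefore
  identical across the tract, producing the long-range homozygosity iHS
  detects. Pool sweeps shift the generative pool frequency before counts
  are drawn.
* Determinism: one integer seed feeds named SeedSequence-spawned streams
  (positions, ancestral, population frequencies, haplotypes, pools, sweep),
  so identical configs give byte-identical outputs across runs and
  platforms.

What the generator deliberately lacks: background linkage disequilibrium
outside swept tracts, recombination maps, demographic history (bottlenecks,
migration), sequencing error in genotypes, and reference bias. Passing
tests therefore certify the estimators and decision logic, and the power of
the screens against the idealized sweep model — not calibrated power on
real chicken data, where LD, uneven coverage and ascertainment would lower
it.

## Problem sizes used in tests and acceptance runs

Synthetic chromosomes of 0.3–1.07 Mb (≈ 2 800–10 000 SNPs at 107 bp
spacing) and 100-replicate power runs on 600 kb chromosomes keep the full
suite under a minute on one CPU while leaving ≥ 100 windows per scan, the
scale at which the nearest-rank top-1 % rule is meaningful. Parameter
recovery uses 20 seeds × ~10 000 sites. iHS power runs use 500 bp spacing
and an 8 kb decay length so the swept tract occupies a small fraction of
the chromosome (standardization needs a neutral background to standardize
against) and curves truncate before the edges.

## Numerical choices and degenerate inputs

* WC84 is undefined when all variance components vanish (both groups fixed
  for the same allele): NaN, excluded from window means and sums.
* Sample sizes are haplotype counts (n/2 diploid individuals internally);
  fewer than 2 haplotypes per group is an error.
* Nearest-rank k uses a 1e-9 guard before the ceiling so (1 − q)·N lands on
  the intended integer despite float representation of q.
* Window means use prefix sums (O(sites + windows)); equality tests on
  their output allow float-epsilon absolute error from cancellation.
* EHH with truncation 0: curves are computed to the edge; with 2 carriers
  EHH is {0, 1}-valued and drops to 0 at the first disagreement.
* The depth band with SD = 0 (all depths equal) retains everything; with
  σ = 0 it retains only sites exactly at the mean.

## Known limitations

The published genome-scale constants (9.3 M SNPs, 139 005 windows, top-1 %
threshold Fst > 0.46, 170 regions, micro/macro means 0.186/0.184) derive
from commercial sequence data that is not publicly available; they are kept
in `sweepscan.published.ORIGINAL_SCALE` as documentation of the original
scale and are not reproduced by the synthetic pipeline, whose thresholds
are empirical quantiles of its own window distribution. The per-region
empirical P is a genome-wide window percentile, not a sampling-theory
p-value, and inherits the usual outlier-scan caveat: under neutrality the
top 1 % is flagged by construction.
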