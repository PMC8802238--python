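# Methods

## The quantity being estimated

For a biallelic locus observed at cohorts born at times t0 < t1 < … < tT−1,
write Δs = p(ts+1) − p(ts) for the frequency change over interval s.  Under
pure drift the Δs are uncorrelated across intervals; directional selection on
a polygenic trait drags linked neutral alleles in a consistent direction, so
sustained selection makes Cov(Δs, Δs+1) > 0 across loci, and a reversal of
selection between intervals makes it negative.  The package estimates the
(T−1)×(T−1) matrix of loci-averaged interval-change covariances per replicate
population, the variance decomposition

    V(Δtotal) = Σs V(Δs) + 2 Σs<t Cov(Δs, Δt),

and the statistic G = 2 Σs<t Cov(Δs, Δt) / V(Δtotal) — the fraction of the
total frequency-change variance attributable to the covariance terms, i.e. to
linked selection.  The decomposition holds exactly (machine precision) on raw
quantities computed from a common SNP set, and G for a single interval is
exactly zero because the covariance sum is empty; both are asserted in tests.

## Estimator conventions

* **Covariance estimator.**  Loci-averaged cross-products of mean-centred
  interval changes (centring across loci; divide-by-L).  Centring affects
  only a rank-one term that vanishes as the loci-mean change does.  It makes
  the estimator exactly polarity-invariant only under flipping *all* loci;
  the uncentred variant (``centered=False``) is exactly invariant under
  flipping any subset, and is also what makes the SNP-weighted per-tile
  decomposition recompose the genome-wide value exactly.
* **Two-stage sampling noise.**  An observed pooled frequency p̂ at pool size
  n (diploids) and read depth d has conditional variance
  p(1−p)·a with a = 1/(2n) + (1 − 1/(2n))/d (n diploids drawn from the
  population, then d reads drawn from the 2n chromosomes).  Since
  E[p̂(1−p̂)] = p(1−p)(1−a), the per-site unbiased heterozygosity estimate is
  p̂(1−p̂)/(1−a); note 1−a = (1 − 1/(2n))(1 − 1/d), the two-stage
  generalisation of the familiar d/(d−1) small-depth factor.  The estimated
  noise variance per site is p̂(1−p̂)/(1−a)·a, using the observed per-site
  depth, not a genome mean.
* **Bias corrections.**  The raw diagonal V(Δs) contains the sampling
  variance of both endpoint estimates; both expected noise variances are
  subtracted.  Adjacent intervals share the observed frequency at the common
  time point; its error ε enters Δs as +ε and Δs+1 as −ε, biasing the raw
  adjacent covariance by −Var(ε); the mean estimated shared-point noise is
  added back.  Non-adjacent entries share no time point and, like
  between-replicate entries (independent pools), receive no correction.
* **Standardization.**  Corrected entries are divided by the loci-mean
  observed heterozygosity p̂(1−p̂) at the earlier of the two intervals' start
  times, which keeps the matrix symmetric.  Loci fixed at the reference time
  are excluded from the standardizer mean but not from the covariance,
  avoiding division by zero without disturbing SNP-set alignment.
* **G.**  Computed from the corrected (unstandardized) matrix by default, so
  numerator and denominator share a scale.

## Site and contig filters

Defaults for real pool-seq data: minimum minor-allele count 2; minimum
coverage 40× in every pool; per-pool maximum coverage at the 90th percentile
of that pool's coverage distribution (the percentile reading of the
"top 10%" idiom; configurable); MAF ≥ 0.02 computed on counts pooled across
a replicate's cohorts (folded); optionally depth ≥ 2n (the number of sampled
alleles); contigs of non-N length ≥ 200 kb; biallelic sites only.  Sites are
retained independently per replicate; between-replicate statistics intersect
loci by (contig, position) with the ref/alt polarity harmonised.  The alt
allele is the pooled minor allele at the first time point summed across
replicates, making the polarity assignment identical in every panel.

For simulated data emitted at ~40× mean depth the analysis preset
(`SiteFilterConfig.for_synthetic()`) relaxes the coverage floor to 25 and
disables the depth ≥ 2n rule: at Poisson(40) depth the 40× floor would
discard half of all sites from depth jitter alone, and 2n ≥ 80 for the
simulated pools would discard everything — both artefacts of the simulator's
depth scale, not of the method.

## Uncertainty

All covariance statistics are smooth functions of per-block sums (counts,
Δ cross-products, noise and heterozygosity sums), so confidence intervals
come from a percentile block bootstrap that resamples 100-kb tiles — the
same tiling as the genome scan — with replacement and recombines block
aggregates (5000 iterations and α = 0.05 by default).  Tiles rather than
SNPs are the resampling unit because linkage disequilibrium makes nearby
SNPs redundant; SNP-level resampling would understate uncertainty.
Percentile intervals are used rather than BCa, matching the simplest
consistent reading of a 95% CI; empirical coverage of the method on i.i.d.
blocks is asserted to lie in [0.92, 0.98].

## Genome scan and outliers

The genome is partitioned into 100-kb tiles (0-based half-open; sync input
positions are 1-based).  Each tile's loci get the same estimator,
corrections and standardization as genome-wide, with per-tile loci means;
tiles with fewer than 10 SNPs are reported missing, never zero.  A tile is
an outlier when the covariance entry of interest exceeds the threshold
(0.01 by default) in **every** replicate; a missing value in any replicate
disqualifies the tile.  BED exports carry per-replicate values, the
replicate mean, and the outlier flag.

## Pooled diversity and differentiation

* **π.**  Sites are first downsampled to a uniform target coverage m
  (default 30) by a multivariate hypergeometric draw on the nucleotide
  counts; sites below target are dropped.  Per covered site at coverage m,
  heterozygosity is m/(m−1)·(1 − Σ(c/m)²) — unbiased for the read-pool
  heterozygosity — with sites counted as polymorphic only when the minor
  allele is seen at least twice (a sequencing-error guard that introduces a
  small, documented downward bias).  Window π = summed heterozygosity per
  covered base (window 10 kb), and windows under 50% covered fraction are
  missing.
* **F_ST.**  Per SNP between two pools, the default is π-based
  (Hudson-type): F_ST = (π_total − π_within)/π_total with within-pool
  heterozygosities corrected by 1/(1−a) for pool size and depth and the
  between-pool term p̂1(1−p̂2) + p̂2(1−p̂1), which is unbiased because the
  pools are independent.  Negative values are clipped to 0 and reported
  alongside the unclipped value.  A read-level Karlsson-style variant is
  provided because the common pooled tooling offers both and the choice is
  not otherwise determined.

## The simulator

`tempocov.synthetic_data` emulates the motivating design: three replicate
forest populations, four age-structured cohorts (birth years 1680, 1850,
1960, 2008), pools of 40–68 diploids sequenced at ≥40× mean depth.  Discrete
Wright–Fisher generations advance the population between cohorts (default
one regeneration per interval, configurable); under a directional regime
individual fitness is exp(±Σ αl·gl) over selected loci with effects drawn
±Uniform(0.5, 1.5) and rescaled so the founder additive variance of log
fitness matches the target V_A.  Recombination is Poisson crossovers per
chromosome at the configured per-bp rate; chromosomes assort independently.
Cohorts are sampled without replacement from the population of their birth
generation; per-site read depth is Poisson and read alleles are binomial
draws from the 2n sampled chromosomes — exactly the noise model the
estimators correct for, which the simulator cross-checks against the closed
form (`expected_noise_check`).

Founder frequencies follow a symmetric Beta(0.5, 0.5).  Founders are either
in linkage equilibrium (default) or drawn from a finite pool of K distinct
haplotypes, optionally per block of a chosen bp length, which injects
standing LD at a controlled scale.  With shared targets the replicates share
founder frequencies, the haplotype pool and the selected-locus map
(a common refugial origin); this shared standing LD is what makes parallel
selection visible *between* replicates.

### Fixture presets and their power reasoning

The linked-selection signal per neutral locus scales roughly as
(per-chromosome V_A / 2) / K per pair of selection generations, while
pooled-sequencing noise on a genome-wide covariance is of order
a/√L.  The presets are sized so the mechanism under test is resolvable at
desk scale:

* **neutral** — N = 10⁴ diploids, 20 chromosomes × 500 loci (10⁴ SNPs over
  200 tiles of 100 kb), founders in linkage equilibrium, depth 40×, pools of
  50.  Used for calibration: corrected standardized covariances' 95% CIs
  should cover zero, and raw adjacent covariances should be negative
  (shared-point bias).  Linkage-equilibrium founders keep tiles independent,
  the assumption of the block bootstrap.
* **sustained / reversal** — N = 1000, 10 chromosomes × 500 loci, K = 16
  founder haplotypes per chromosome, 50 selected loci, two regenerations per
  interval.  Sustained: all intervals directional(+) at V_A = 0.2.
  Reversal: (+, −, neutral) at V_A = 0.6 — stronger because its signature is
  a single matrix entry with no averaging over adjacent entries, so per-run
  sign recovery needs a larger planted effect.
* **parallel** — as above with V_A = 0.6 concentrated in the first interval
  only (a single severe episode, as in juvenile-stage viability selection),
  shared founders and targets across the three replicates.
* **scan** — 10 chromosomes × 5 Mb (500 tiles), 2000 loci per chromosome,
  K = 16 per 100-kb block so LD — and hence the signal — is tile-local,
  ~1 crossover per chromosome per meiosis, 50 selected loci spread evenly
  over the first 500 kb of chr1, V_A = 1.5 over three regenerations per
  interval, pools of 68 at 100×.  The outlier threshold for this fixture is
  tuned as a robust upper fence of the null tile values
  (median + 2.5·1.4826·MAD).

### What the simulator does not model

Overlapping generations, pollen flow between cohorts or from external
populations, seed dormancy, age-dependent fitness, spatial structure within
a forest, and sequencing artefacts beyond depth jitter (no mapping bias,
base errors or N/del counts).  Passing tests therefore show that the
estimators recover the signatures the discrete-generation linked-selection
model predicts under realistic pooled sampling noise — not that real forest
data are free of the confounders above.

## Numerical choices and degenerate inputs

Noise estimates are undefined at depth 1 (1−a = 0) and propagate NaN; the
filters keep such sites out.  A standardizer over zero non-fixed loci yields
NaN for the affected entries.  Covariance matrices require ≥ 2 loci and ≥ 2
time points; the bootstrap requires ≥ 2 blocks; overlapping non-identical
period pairs between replicates are refused.  Allele-pair ties at the
polarity reference are broken toward the higher base index,
deterministically.  All randomness flows through seeded NumPy generators;
per-replicate streams are spawned from one seed sequence, so every result is
bit-reproducible for a given configuration.

## Problem sizes used in the verification suite

Test and acceptance runs use the preset sizes above: 20 neutral runs for
calibration, 20 runs each for sustained and reversal signs, 5 V_A levels × 6
runs for the dose-response rank test, 5 parallel-regime runs, one scan
fixture, 10⁶-draw Monte-Carlo oracles for the noise model, and
1000-iteration bootstraps (the 5000-iteration default is for real analyses).
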