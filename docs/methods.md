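# Methods

`coastgen` re-implements, as a tested pipeline over synthetic data, the
analytical core of a landscape-genomics study of thermal adaptation in a
coastal marine fish: a windowed selection-signature scan contrasting a
cold (northern) and a warm (southern) population, a composite selection
score, positively-selected-region and -gene calling, genotype–environment
association against sea-surface-temperature covariates, and a
multivariable dissection of isolation by distance (IBD) versus isolation
by environment (IBE). This note documents the models, the parameter
choices that matter, and what the synthetic experiments do and do not
demonstrate.

## Windowed selection statistics

All scan statistics are computed on a sliding-window grid of 50 kb
windows advancing by 10 kb, anchored at position 1 of each chromosome;
a final partial window is kept if it spans at least one step. The
windows deliberately overlap: a sweep signal therefore appears in a run
of consecutive windows, which the region-calling step merges.

**FST.** Weir & Cockerham's (1984) two-population variance components
(a, b, c) are computed per SNP from sample sizes, allele frequencies and
observed heterozygosity; windowed FST is the ratio of sums Σa/Σ(a+b+c)
over the window's SNPs. SNPs monomorphic across both populations
contribute nothing. The ratio-of-sums form (rather than averaging
per-SNP ratios) is the standard choice because per-SNP ratios are noisy
and biased at low minor-allele frequency.

**Nucleotide diversity and ω.** Per-SNP π is the unbiased expected
heterozygosity 2p(1−p)·n/(n−1) with n the non-missing haplotype count;
window π divides the sum by the full window span (the windowed-π
convention: invariant sites count as zero diversity). ω = log2(π_A/π_B)
flags diversity loss: a hard sweep in the northern population drives
ω negative. Windows where either π is zero leave ω undefined; such
windows are excluded from percentile ranks rather than given an
arbitrary extreme value.

**Tajima's D.** The standard (1989) statistic from the number of
segregating sites and the mean pairwise difference within each window,
with the a1…e2 constants from the population's full haplotype count.
Windows without segregating sites are missing.

**EHH, iES and Rsb.** EHH around a focal SNP is the probability that two
random carriers of the focal allele are identical over the intervening
sites, computed exactly from haplotype group counts (Σ C(n_h,2)/C(n_c,2)).
The site statistic EHHS is the allele-frequency-weighted average of the
two per-allele EHH curves (Tang-style); iES integrates EHHS over
physical position by the trapezoid rule on both sides of the focal SNP
until EHHS falls below 0.05 (configurable), never crossing a chromosome
boundary, with a hard cap (default 1000 SNPs per side; the pipeline uses
300 — at the default density of one SNP per 500 bp the EHHS of any
non-swept locus has decayed far below the cutoff well before the cap).
Rsb is ln(iES_A/iES_B) standardized genome-wide; the centering statistic
is the median by default (configurable to the mean), and standardization
precedes window averaging. Integration is in physical bp because no
genetic map exists for the system being emulated.

## Composite selection score

Each contributing statistic (FST, |ω|, |Rsb|; columns are oriented so
that larger = more selected) is converted to fractional ranks
r = rank/(n+1) (average ranks for ties, which keeps the normal quantiles
finite), then to z = Φ⁻¹(r). The mean z̄ across the k statistics is
rescaled by √k so that under independent null statistics the rescaled
mean is standard normal; p = 1 − Φ(z̄√k) and CSS = −log10 p. The √k
rescaling is this package's resolution of an ambiguity in how "compared
against a normal distribution" is to be read; the acceptance check
verifies the calibration empirically (type-I rate 0.049 at nominal 0.05
under a three-statistic null with n = 2000 windows and 200 replicates).
Note that rank statistics across windows are not strictly independent
(overlapping windows share SNPs); the calibration experiment uses
independent nulls and measures the transform itself.

## PSR and PSG calling

A window qualifies as part of a positively selected region when FST,
|ω| and |Rsb| are all at or above their genome-wide 95th percentiles.
The genome-wide (not per-chromosome) percentile is used. Side
assignment uses sign concordance: ω < 0 with Rsb > 0 means diversity
lost and haplotypes extended in the northern population (north-side
sweep); the mirror pattern is south-side; discordant combinations are
discarded with a logged count. Overlapping or abutting qualifying
windows of the same side merge into maximal regions (a configurable
max-gap, default 0, allows bridging). Genes overlap a region by ≥ 1 bp
(1-based inclusive coordinates throughout the reported tables) to be
called positively selected; the CSS is reported alongside the three base
statistics but does not participate in the qualification rule.

## Genotype–environment association

**Bayes factors.** Per-site allele frequencies are standardized per SNP
by the across-site mean (√p̄(1−p̄) scaling) and whitened by Ω^(−1/2),
where Ω is the across-site covariance of the standardized frequencies —
the same shared-drift correction logic as covariate-aware Bayesian
GEA models. For each SNP a linear model of the whitened frequencies on
the whitened covariate is compared with the intercept-only model by the
BIC approximation BF = exp((BIC₀−BIC₁)/2), reported as 10·log10 BF
deciban. The decision rule is strict: BF > 20 dB ("decisive"). This
deterministic approximation replaces an MCMC tool; an externally
computed BF table can be supplied instead. Ω is ridge-regularized
(1e−8) if near-singular.

**RDA outliers.** Individual dosages (site covariates broadcast to
samples) are regressed on the standardized covariates; the SVD of the
fitted matrix gives the constrained axes (retained axes default to the
number of covariates). SNP loadings are z-scored per axis and summed as
Σz², compared against chi-square with df = retained axes. Under a null
simulation the p-values are uniform (KS-tested).

**Intersection.** A candidate SNP needs a decisive BF for at least one
covariate AND RDA p below α (default 0.001, a choice made here — the
upstream convention is not fixed); candidates are tagged by covariate.
Genes within 5 kb (inclusive) of a candidate are reported.

## Geographic and climatic predictors

Great-circle distance uses the haversine with R = 6371.393 km.
Meridional distance is 2πR·|Δlat|/360. Coastline distance is the
shortest 8-connected path through water cells of a rasterized coastal
strip (axial step = cell size, diagonal = √2·cell), so peninsulas and
land barriers lengthen the path; any locally length-preserving planar
projection is acceptable at the ~1000 km scale, and the synthetic tests
use a flat plane so no projection error enters. SST climatology per
site: SST_max and SST_min are the mean over calendar years of each
year's extreme daily value (configurable to overall extremes), SST_med
the median of all days; series must span ≥ 1 year with no gap > 30 days.

## IBD/IBE modelling

Genetic distance between sites is Weir–Cockerham FST linearized as
FST/(1−FST), with FST computed by ratio-of-sums within each chromosome
and chromosome values averaged weighted by SNP count.

**Single-factor OLS** reports the conventional coefficient table, R²,
adjusted R², Gaussian log-likelihood, AIC = 2k − 2ℓ and
BIC = k·ln n − 2ℓ. Pair observations from S sites are not independent
(C(S,2) pairs); the plain p-values are reported as the field convention,
and the commonality module provides site-bootstrap intervals as the
honest uncertainty.

**Regularized least squares.** Predictors are z-scored, the response
centred. Stage 1 is LASSO with 5-fold cross-validated penalty (fixed
seed); zero-coefficient predictors are dropped. Stage 2 is an elastic
net with mixing 0.5 on the survivors. SE/t/p follow the post-selection
OLS-refit convention; dropped predictors get coefficient 0 and p = 1.

**GDM.** Each predictor enters through three monotone I-spline basis
functions (normalized antiderivatives of degree-1 B-splines with knots
at the min/median/max of the site values); the pair term is
|I(x_i) − I(x_j)|, the response is max-normalized to [0,1) (divided by
1.01·max), and the link is d = 1 − exp(−η). Fitting is iteratively
reweighted non-negative least squares on the link scale (Gauss–Newton
with NNLS subproblems, Δdeviance < 1e−8). A predictor's fitted spline
maximum height (the sum of its non-negative coefficients) measures its
total contribution; importance is the mean percent drop in deviance
explained when that predictor's site values are permuted across sites,
and p is the (add-one-smoothed) fraction of permutations whose deviance
explained matches or beats the observed fit. Distances that have no
natural site-level value (coastline, great-circle) are represented by
1-D site coordinates along the coast (cumulative chain distance), so
pair differences of the coordinate reproduce the along-coast distances;
this is exact for sites ordered along one coastline, which both the
emulated design and the generator satisfy.

**PSR vs non-PSR contrast.** Pair FST is recomputed by ratio-of-sums
over the windows inside (resp. outside) the called regions, linearized,
and a GDM fitted to each division; spline maximum heights are compared
side by side.

**Commonality analysis.** All-subsets R² over the 2^p − 1 predictor
subsets; the commonality components solve the linear system
R²(A) = Σ_{S∩A≠∅} C(S) exactly, so components sum to the full R² to
machine precision. Structure coefficients are correlations of each
predictor with the fitted response; Pratt = β·r; relative weights use
Johnson's orthogonal-approximation decomposition (they also sum to R²).
Pairwise-difference matrices of squared structure coefficients and
relative weights are reported. Bootstrap intervals resample *sites*
(not pairs — resampling pairs breaks exchangeability) and rebuild the
pair table each draw; duplicate-site pairs are dropped.

## Synthetic data generator

The generator produces every input the analysis reads, with known truth.

*Demography.* Six demes (sites) along a latitudinal coastline, ten
diploid samples each, deme size N = 100, 200 generations of forward
binomial drift with symmetric nearest-neighbour migration m = 0.1,
ancestral frequencies Beta(0.8, 0.8) clipped to (0.02, 0.98). The two
northern demes form the cold population, the two southern the warm one,
the middle demes an intermediate population. This yields mean windowed
north–south FST ≈ 0.12 and monotone IBD along the chain. Haplotypes are
drawn from per-deme pools of 2N Bernoulli haplotypes — a transparent,
seed-stable forward model chosen over a coalescent because the scan
consumes rank-based signals, not fine-scale LD structure.

*Genome.* Two chromosomes of 5 Mb with 20,000 SNPs at uniform random
positions (one SNP per 500 bp on average).

*Sweeps.* Ten north-side and ten south-side hard sweeps: in each target
deme a fraction q₀ = 0.95 of haplotypes is overwritten by one shared
core haplotype (the same core across the sweep's demes — a single
selective event), each site keeping the core allele with probability
exp(−d/r), r = 300 kb. The planted interval is 50 kb (half-width 25 kb),
matching the scan window so each sweep owns at least one undiluted
window; the total sweep footprint (~10% of windows) stays close to the
5% tail the percentile rule can flag. These choices make the planted
signal what it claims to be — a strong, near-fixation hard sweep — while
keeping the neutral background dominant; with much wider intervals the
95th-percentile cutoffs sit inside the sweep distribution and recall is
structurally capped regardless of the detector.

*Environment-associated loci.* Twenty loci (ten in the GEA replicate
design) whose allele frequencies follow the latitudinal cline from 0.95
in the coldest deme to 0.05 in the warmest. The cline is imposed on the
*sampled* haplotype counts (up to rounding), not only on the underlying
pool: with 20 haplotypes per site, binomial sampling noise alone
collapses a perfect pool-level cline from ~1500 dB to ~16 dB of Bayes
evidence, so "decisively associated locus" is only a meaningful planted
signal if the realized sample frequencies carry it. The detector's null
calibration is tested separately.

*SST.* Daily series over 10 years per site:
T(t) = 18 + 8·s(t) − g(t)·(lat − lat̄) + N(0, 0.5), where s(t) is an
annual sinusoid and the latitudinal gradient g(t) interpolates between
0.15 °C/deg in summer and 0.9 °C/deg in winter — reproducing the
characteristic asymmetry of the emulated seas, where the north–south
SST difference is large in winter and small in summer. Consequently
ΔSST_min between sites far exceeds ΔSST_max.

*Coast raster.* A water corridor (cell size 20 km at the synthetic
scale) following a bulging coastline polyline, so the along-coast path
between end sites exceeds the great-circle chord.

*Determinism.* All randomness derives from one seed through named
`SeedSequence` children (global drift, per-deme pools, env planting,
sweeps, environment); equal seeds give byte-identical emitted bundles.

*Direct pair-table generators.* For the IBD/IBE recovery experiments a
separate generator draws 14 sites along a coast and builds pair tables
with gdist = w₁·f(Δcoast) + w₂·g(ΔSST) + noise (saturating monotone f,
g; default w = 0.6/0.4, noise SD 0.02), and a region-contrast variant
plants SST-driven differentiation inside flagged windows and
coast-driven differentiation outside. The 14-site / 5-sample GEA
replicate design mirrors the multi-site sampling of the emulated study
(14 sites, 5–10 genomes each) because the Bayes-factor power is set by
the number of sites, not the number of SNPs.

## What the synthetic experiments show — and what they do not

Passing recovery tests show that the implemented estimators are correct
(they match independent oracles to 1e−8), that the decision rules are
calibrated under their nulls, and that the pipeline recovers planted
signals of the designed strength under the stated demography. They do
not show that the pipeline would recover selection in real resequencing
data: real genomes have recombination-driven LD structure, missing
genotypes, variant-calling artifacts, soft/partial sweeps and
demographic confounding that the forward generator deliberately omits.
The generator's LD background is weaker than real LD (haplotype pools
rather than recombination), which makes the Rsb null tighter than in
real data; the planted sweeps are correspondingly near-fixation events.

## Problem sizes and run times

The default bundle (2 × 5 Mb, 20k SNPs, 60 samples) is scanned in
~60–90 s on one CPU; the full pipeline including GEA and IBD/IBE stages
completes in a few minutes. Permutation and bootstrap counts default to
5000 in the library API (the emulated study's setting); the pipeline
driver and the recovery experiments use 200 permutations / 200
bootstraps and 20–50 replicates, which is sufficient for the qualitative
assertions they make. The EHH integration cap, window sizes, thresholds
(95th percentile, 20 dB, α = 0.001, 5 kb radius) and the regression
settings (elastic-net mixing 0.5, 5-fold CV) are all exposed in
`RunConfig` / function signatures.

## Known limitations

- The BIC Bayes-factor approximation is cruder than full MCMC evidence
  at very small site counts; its absolute dB scale is comparable only
  in order of magnitude, though the >20 dB decision behaves as intended
  under the planted/null contrast.
- Per-axis z-scoring of RDA loadings means a SNP with exactly zero
  loading has a small positive statistic (the mean-loading offset); the
  chi-square reference is approximate, as in the common practice it
  mirrors.
- GDM site-coordinate embedding of path distances assumes sites ordered
  along one coastline; a branching coast would need true
  distance-matrix splines.
- `ld_prune` is the greedy windowed r² rule; it reproduces the
  convention of the common tooling but is O(windows × pairs) in Python
  and intended for the pruned-set sizes used here.
- The pair-table OLS p-values inherit the usual pseudo-replication of
  distance regression; use the bootstrap intervals for inference.
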