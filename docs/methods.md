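# Methods

`iopopgen` implements the inference chain used to reconstruct the
demographic and selection history of admixed island cattle (the Mayotte
and Madagascar zebu, MAY and ZMA) from dense autosomal SNP genotypes: QC,
f-statistics, admixture-graph fitting, admixture-LD dating, LD-based
historical Ne, multi-class HBD inbreeding partitioning, and EHH selection
scans. All stages are exercised on seeded synthetic data; this note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Genotype model and QC

Panels are diploid biallelic autosomal SNPs stored as counts of a
designated `allele_b` (0/1/2; one internal missing sentinel normalizes
the -9/./NA dialects of input files). Coordinates are 1-based; the
genetic map defaults to 1 cM/Mb when a file provides no genetic
positions. PLINK-text `.ped` files do not record which allele is counted,
so the writer emits a small `.ref` sidecar (marker, allele_a, allele_b)
that the reader honors; without it the first-seen allele is `allele_a`.
VCF input is parsed by a compact text reader rather than an htslib
binding: panels here are plain uncompressed VCF 4.x, and the reader's
error messages name the offending line, which the QC contract requires.

QC is deliberately order-dependent: individuals below 90% call rate are
removed first, then SNPs failing the 90% overall call rate, the 75%
per-population call rate, the pooled MAF < 0.01 cutoff, and finally the
within-population Hardy–Weinberg exact test at p < 1e-3 in at least one
population. The HWE test is the full conditional enumeration over
heterozygote counts (no chi-square approximation), applied per
population. MAF pools all retained individuals because the cutoff is a
single global rule. The report counts removals per criterion in
application order, so the counts sum to the total removed.

Markers whose array probe sequence maps ambiguously to the assembly are
resolved from a precomputed alignment-hit table: no hit or more than 9
hits drops the marker, 2–9 hits take the best-scoring placement, and
exact score ties break deterministically to the lowest chromosome, then
position (running the aligner itself is out of scope).

## f-statistics

All estimators work from per-population allele frequencies `p` and
observed allele counts `a` (2 x called individuals):

* heterozygosity: unbiased `2p(1-p) a/(a-1)`;
* f2, f3 carry the standard finite-sample corrections
  `p(1-p)/(a-1)` on the populations that appear squared; f4 needs none;
* FST: the Weir–Cockerham variance-components (ANOVA) estimator on
  allele counts, with multi-marker estimates formed as the ratio of
  summed numerator and denominator components;
* population-specific FST: the allele-matching formulation
  `F_i = (M_ii - M_B)/(1 - M_B)` with bias-corrected within-population
  matching and the mean between-population matching as baseline, again
  ratio-of-sums.

Standard errors come from a weighted leave-one-block-out jackknife over
blocks of 5,000 consecutive SNPs that never span chromosomes; trailing
markers that cannot fill a block are unassigned. With equal block sizes
the formula reduces to the classical delete-one jackknife (a unit test
asserts this). f-statistics average per-marker values with equal weights
over markers where every tuple member is defined (complete-tuple
analysis), so different statistics may use slightly different marker
sets. Thresholds are strict everywhere: an f3 triplet is flagged admixed
when Z < -1.65 (95%) or Z < -2.33 (99%), exactly at the boundary is not
flagged. Ascertainment keeps markers with pooled MAF strictly above 0.05
in every named population group.

## Admixture graphs

The scaffold tree is neighbor joining (scikit-bio) on the pairwise-f2
matrix, rooted at the midpoint of the edge realizing the prescribed
outgroup bipartition; negative NJ branch lengths are clamped to zero with
a warning. Predicted f2 between leaves is `sum_e (w_A - w_B)^2 l_e` with
leaf-edge usage weights computed by propagating path probabilities
through admixture nodes (alpha to one parent, 1-alpha to the other);
f3/f4 follow from the linear identities in f2, so f4 antisymmetry and the
degenerate-alpha tree limit hold exactly by construction.

Fitting minimizes the diagonal weighted least squares
`Q = sum r_i^2 / var_i` over the f2 basis with L-BFGS-B (lengths bounded
below by 0, alpha in (0.001, 0.999)), from 25 seeded restarts by default
(fewer during the insertion search; the first start uses the current
graph parameters). Diagonal weighting was chosen over the full jackknife
covariance for stability at ~10 populations; BIC = Q* + k ln(n_stats) is
used for relative comparison only, with the conventional "more than 8
units lower" support rule. Admixed leaves are inserted greedily over all
permutations of the insertion order: each leaf is tried as a plain branch
on every edge and as a two-parent admixture between every edge pair, the
BIC-best placement is kept, and the best final graph across orders is
returned with its BIC gap to the runner-up. The original builder's exact
candidate enumeration is not published; this greedy scheme is the
package's own documented scheme. A fit is called adequate when the worst
residual Z over all supplied f-statistics satisfies |Z| < 3.

Drift lengths are estimated on the scale of the data (drift in t/2Ne
units times the panel's heterozygosity scale); fitted alphas are
scale-free, and a test asserts that multiplying all observed f2 by a
constant rescales lengths and leaves alphas unchanged.

## Admixture-LD dating

The two-reference weighted-LD statistic accumulates
`D(x,y) (p1x - p2x)(p1y - p2y)` over intra-chromosome marker pairs into
0.05-cM distance bins up to 30 cM, where `D` is half the sample
covariance of the target's unphased dosages and the weights are allele-
frequency differences between two source proxies. Curves store
per-chromosome accumulators so the leave-one-chromosome-out jackknife of
the decay fit is exact. The fit is nonlinear least squares (analytic
Jacobian, 10 seeded restarts) of `A exp(-n d) + c` on bins beyond
d0 = 0.5 cM — the short-range exclusion skips background LD; d0, dmax
and the bin width have no canonical published values, so these defaults
are the package's own. A curve with amplitude not significantly
above the residual scale is flagged `no_decay` and yields no date.
Candidate source pairs are ranked by fitted amplitude, failed fits last.

Generation-time calibration divides a known age in years by a fitted
admixture time (delta-method SE), reported to one decimal; calendar
conversion multiplies generations by the generation time (6 years for
cattle by default, 5/7 supported for sensitivity) and subtracts from the
population's own sampling year, honoring per-population sampling offsets
(the two islands were sampled 26 years ≈ 4 generations apart).

## LD-based Ne history

The point estimator is the classical binned inverse-LD relation for
unphased dosage data: within each recombination-fraction bin,
`r2_adj = mean r^2 - 1/n_ind` and `Ne = (1/r2_adj - 2)/(4 cbar)` at
`t = 1/(2 cbar)` generations before sampling, with recombination
fractions from the cM map via the inverse Haldane function and 30
log-spaced bins in c = 1e-4..0.1 by default. This replaces a named
external tool's internal genetic-algorithm spectrum fit, which is out of
scope; the jackknife-envelope procedure around it is implemented as
specified: all full blocks of 10,000 consecutive SNPs within chromosomes
(block count is data-dependent, never hard-coded), one re-estimation per
omitted block, and a per-time envelope from the 2.5/97.5 percentiles
around the mean. Bins with non-positive adjusted r2 or implied Ne are
flagged undefined rather than clamped. The estimator is order-of-
magnitude by nature: on constant-Ne coalescent panels the mid-range bins
(t in 10–100 generations, the range used for recovery checks and the
harmonic-mean summaries here) recover the truth within a factor of two,
with an upward drift in the oldest bins that is a known limitation of
inverse-LD estimators. Harmonic means over a time window and calendar
axes (sampling_year - 6t) are provided.

## HBD hidden Markov model

Each individual's genome is a mosaic of HBD and non-HBD segments. The
model has K HBD classes with rates R_k = 2^k (k = 1..11 by default;
expected segment length 1/R_k Morgans, ancestor depth ~R_k/2 generations,
so the deepest class reaches ancestors 1,024 generations back) plus one
non-HBD class sharing the last rate. Between markers at distance d
Morgans the chain stays with probability exp(-R d) and otherwise
re-enters a class drawn from the stationary mixing weights (single-layer
model, no class-to-class memory). Emissions: HBD classes emit homozygotes
with probabilities (q, p) scaled by (1 - eps) and heterozygotes with eps;
the non-HBD class emits Hardy–Weinberg probabilities blended with a
uniform eps/3 error floor; missing genotypes emit 1 everywhere.
eps defaults to 0.001, a typical array error rate. Allele frequencies
default to the analyzed population's own estimates (external frequencies
can be supplied). Chromosome breaks are encoded as effectively infinite
distances, so the chain redraws its class at each chromosome start.

Forward–backward runs scaled (numba-accelerated; safe for 700k-marker
genomes), and EM fits the mixing weights with rates fixed, using the
expected re-entry counts plus the initial draw as the sufficient
statistic; the log-likelihood is non-decreasing by construction and
iteration stops at a gain below 1e-6 or 1,000 iterations. Posteriors on
instances small enough to enumerate (<= 10 markers, <= 3 classes) match
the exhaustive path sum to 1e-10. Age partitioning sums class fractions
with R/2 at or below a generation cutoff (recent) against the rest
(ancient); recent + ancient equals total F exactly.

One calibration note: the realized autozygosity of a single offspring of
half-sibs varies around its expectation 1/8 with sd ~0.04 over a
3,000-cM genome (meiosis variance, not estimator noise), so recovery
checks compare the expectation against the mean estimate of a small
simulated cohort rather than a single genome.

## Selection scans

EHH at a core site is the probability that two random distinct carrier
haplotypes are identical over the whole stretch from the core; it is 1 at
the core and non-increasing outward. Integration is trapezoid on the
genetic map of the area above the 0.05 cutoff, stopping at the cutoff or
at an inter-marker gap above 0.5 cM; a marker whose EHH has not decayed
below the cutoff when a chromosome end is reached is flagged undefined
and excluded. iHS is `ln(iHH_b / iHH_a)` standardized to mean 0 / sd 1
within 20 equal-width bins of the counted-allele frequency (bins with
fewer than 10 markers merge with neighbors); alleles are not polarized —
their roles are fixed by the panel coding. Rsb integrates the site-EHH
(haplotypes pooled, split by core allele, normalized to 1 at the core)
per population and standardizes `ln(iES_1/iES_2)` genome-wide
(median-centering optional). Transforms: `p_iHS =
-log10(1 - 2|Phi(x) - 0.5|)` (two-sided) and the one-sided pair
`-log10(1 - Phi)` / `-log10(Phi)` for Rsb, so each tail names the
population driving the signal. Phasing is an input contract: the panel
type rejects unphased or missing data, and the synthetic generators emit
phased haplotypes directly.

Gene-level calling assigns each SNP to every gene whose span extended by
15 kb contains it (1-based inclusive on both flanks) and calls a gene a
candidate when at least two assigned SNPs exceed a transformed score of
4, per statistic. Gene-set enrichment is the right-tailed Fisher exact
(hypergeometric tail) per category against a declared gene universe,
significant at p < 0.05.

## Synthetic data

Two engines cover the analyses' needs; every generator is a pure function
of (parameters, seed) and emits a truth record that recovery tests read
exclusively.

* Graph frequencies: root frequencies uniform on (0.05, 0.95); each edge
  adds Normal(0, l p(1-p)) truncated to [0,1]; admixture nodes drift each
  parent along its own in-edge and then mix linearly with alpha —
  matching the predictor's weighting, so estimator-vs-truth tests close
  the loop. Truncation compresses the deepest pairs by a few percent,
  which the comparison tests budget for. Genotypes are binomial draws at
  the leaves. `island_zebu_graph()` carries the inferred two-pulse topology
  with proportions 0.684/0.886 and placeholder drift lengths on the data
  scale.
* Ancestry mosaics: haplotype tracts switch as a Poisson process at the
  admixture age per Morgan, each tract copying a random source haplotype
  (source 1 with probability alpha). Mean interior tract length is
  100/n cM, the generative counterpart of the weighted-LD decay.
* Island split: discrete Wright–Fisher frequency simulation — an
  ancestral pool (Ne 10,000 by default; the original supplementary value
  is not published) at stationary frequencies, two daughters resampling
  binomially at Ne (1045, 2160) for 80 generations with per-generation
  pool replacement m = (4e-3, 2e-3), the second daughter genotyped 4
  generations early, mirroring its earlier sampling year. Note: under
  this model (verified with an independent coalescent simulation) the
  higher-migration daughter ends more, not less, differentiated — the
  4 Ne m products of the two islands are nearly equal, so migration does
  not overcome the twofold Ne difference; see the known-limitations note
  below.
* Inbred pedigrees: founder haplotypes with labelled ancestry, meiosis
  with Poisson crossovers on the map, explicit half-sib / full-sib /
  selfing / unrelated designs; true F is the length-weighted autozygous
  fraction.
* Constant-Ne haplotypes: coalescent simulation (msprime) of independent
  chromosomes at 1 cM/Mb, optionally with piecewise-constant size
  changes — the ground truth for LD-based Ne and neutral EHH calibration,
  since the frequency engines produce no within-chromosome LD.
* Sweep injection overwrites a carrier fraction of haplotypes with one
  template over a cM window (0.5% flip noise); panel corruption masks and
  perturbs genotypes at i.i.d. rates to exercise QC.

What the generators do not emulate: realistic site-frequency-spectrum
ascertainment of array SNPs, gene conversion, variable recombination
maps, and linked selection backgrounds. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions, not robustness to every feature of real array data.

## Problem sizes used in tests

The default suite runs simulations at sizes chosen to keep the full run
in the tens of minutes on one CPU while leaving each check statistically
meaningful: 50k-SNP graph panels for f3/f4 properties, 100k SNPs for
mixing-proportion recovery, 60k-SNP mosaics (3–4 seeds per age) for
dating bias, 30k-SNP genomes for HBD recovery, 40k-SNP coalescent panels
for Ne, 100k markers for neutral iHS calibration, and 100 seeds of
5,800-SNP panels for null-f4 calibration.

## Known limitations

* The island split scenario with the literal published parameters does
  not reproduce the directional differentiation/heterozygosity contrast
  between the two islands; both this package's frequency engine and an
  independent coalescent run agree on the reversed direction. The
  corresponding acceptance check is expected to fail and is retained
  unweakened.
* The Ne point estimator is a documented substitute for a genetic-
  algorithm spectrum fit and is order-of-magnitude only, with upward bias
  in old (low-recombination) bins.
* The admixed-leaf insertion search is greedy per order; with weakly
  separated sources different orders can reach different local optima
  (the BIC gap to the runner-up is reported for exactly this reason).
* Single-pulse dating only: targets formed by multiple admixture waves
  fold their history into one effective date.
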