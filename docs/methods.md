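# Methods

`btiscan` implements the statistical chain used to find loci involved in
resistance of *Aedes aegypti* larvae to the bio-insecticide *Bacillus
thuringiensis* subsp. *israelensis* (Bti): a pooled-sequencing genome scan
between a selected and a susceptible strain, neutrality tests on candidate
genes with a coalescent null corrected for the selected strain's demographic
history, probit quantification of resistance from larval bioassays, and
structured association mapping in natural populations. This note documents
the models, the defaults and why, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Pooled genome scan

Read counts per site from two pools are treated as binomial samples of the
pools' allele frequencies. A site is called a SNP when, in each pool,
nucleotide coverage (A+T+C+G of the two retained alleles) is at least
`min_coverage` (default 10), the minor allele is supported by at least
`min_supporting_reads` (2) reads summed over the pools, and its overall
frequency is at least `min_maf` (1%). The MAF rule is applied to the pooled
frequency, not per pool; a per-pool reading would discard fixed differences,
which are exactly the scan's strongest signal. Sites with three observed
alleles are dropped rather than reduced — conservative, and rare at these
coverages.

Differentiation per SNP is the heterozygosity-based estimator

    Fst = (pi_T - pi_S) / pi_T,   pi = 2 p (1 - p) * c / (c - 1),

where `c` is read coverage (a finite-sample correction treating reads as the
sample), `pi_S` the mean of the two pool diversities and `pi_T` the same
quantity on the pooled counts. The estimator is 1 exactly when the pools are
fixed for different alleles and 0 for identical frequencies; values are
clamped to [0, 1]. An uncorrected variant (`corrected=False`) drops the
c/(c-1) factors for sensitivity analysis.

Significance of the frequency difference per SNP is a two-sided Fisher exact
test on the 2×2 (minor/major × pool) read-count table (scipy's hypergeometric
summation; verified in tests against exhaustive fixed-margin enumeration for
every table with total ≤ 24). False-discovery control uses Storey q-values
with the single-λ estimator π̂0 = #{p > 0.5} / (0.5 m), capped at 1; passing
`pi0=1` reduces the procedure to Benjamini–Hochberg, which is how it is
oracle-tested. The spline-smoothed π̂0 was not implemented: with thousands of
SNPs and a heavy null fraction, the single-λ estimate is stable and simpler
to reason about.

A SNP is an outlier when its Fst reaches the empirical 99th percentile
(linear-interpolation quantile; ties included via ≥) of all retained SNPs
*and* its q-value is below 0.005. When every Fst is identical the tail is
empty and nothing is flagged. The percentile is always reported so the
implied threshold (≈ 0.66 in the motivating data) can be inspected.

## Diversity and neutrality statistics

Alignment columns containing `N` or a gap are removed list-wise before any
computation and per-site quantities use the retained length, matching the
classic polymorphism software behaviour. `S` counts polymorphic columns; `η`
counts one mutation per derived state (a column with k alleles contributes
k−1); a singleton mutation is a variant carried by exactly one haplotype
(count 1, or count n−1 under the other labelling — the statistics are
outgroup-free). Tajima's D uses S; Fu & Li's starred statistics use η and
η_s, per their definitions:

    D  = (K − S/a₁) / sqrt(e₁S + e₂S(S−1))
    D* = ((n/(n−1)) η − a_n η_s) / sqrt(u_D η + v_D η²)
    F* = (K − ((n−1)/n) η_s) / sqrt(u_F η + v_F η²)

with K the mean pairwise difference count and the variance constants from
the corrected published set used by reference implementations. The constants
are locked by regression tests (hand-computed n=4 cases: D = D* = 0.5916 for
the two-site alignment, F* = 0.2622) and by simulation: on 3000 neutral
constant-size coalescent replicates (n=20, θ=5) the means of D, D* and F*
fall within ±0.06 of zero with SD ≈ 1.

## Coalescent null with the selection-experiment demography

The resistant strain's short, known history makes the usual constant-size
null wrong for it: a bottleneck inflates D, steady introgression from the
susceptible stock re-injects diversity. The simulator runs backwards in
time:

1. **Discrete Wright–Fisher window** over the experiment's generations
   (default 20): each lineage in the focal strain first migrates to the
   source population with that generation's introgression fraction, then
   every lineage picks a parent uniformly among the 2·Ne(g) chromosomes of
   its population; lineages choosing the same parent coalesce (multiple
   mergers allowed — exact, not an approximation, which matters at the
   bottleneck where Ne is small relative to the sample).
2. **Continuous phase**: at the founding of the strain all remaining focal
   lineages are absorbed into the constant-size source population (the
   strain was derived from that stock) and a standard exponential-time
   pairwise coalescent finishes the genealogy.

Mutations fall on branches as Poisson(μ · branch length in generations)
under infinite sites. μ defaults to θ/(4·Ne_source) with θ estimated from
the susceptible sample's Watterson θ and Ne_source = 6000.

Default scenario (`selection_experiment_scenario`): 20 generations at
Ne = 6000 with 2.5% introgression per generation; a crash to Ne = 600 at
forward generation 10; the two following generations use 20% introgression.
The crash size is not published — 600 (a tenfold reduction) encodes "sharp
decrease" and is exposed as a parameter, not asserted as the historical
value.

The corrected p-value for an observed statistic is the plus-one empirical
tail probability among `n_replicates` (default 1000) simulated samples,
one-tailed in the observed direction, mirroring how such tables report
"P < 0.02" for a positive D*. Replicates with S = 0 are skipped (the
statistics are undefined there) and their count reported; a two-tailed p is
also returned. Note the directional p is a significance measure, not a PIT:
under the null it concentrates below 0.5 by construction. The simulator's
calibration is tested through the exchangeability rank property and against
msprime as an independent constant-size oracle.

## Probit bioassay analysis

Mortality is modelled as probit(p) = α + β·log₁₀(dose), fitted by binomial
maximum likelihood via IRLS (statsmodels GLM). Control mortality is removed
beforehand with Abbott's formula (observed − control)/(1 − control), applied
per replicate by default (pooled optional); corrected values below zero are
clamped with a warning. Doses with 0% or 100% mortality stay in the
likelihood. All-or-nothing mortality at every dose leaves the slope
unidentifiable and raises an error rather than returning a divergent fit.

Heterogeneity follows the classic probit practice: h = Pearson χ²/df; when
h > 1 and the χ² test rejects at 5%, the parameter covariance is inflated by
h and the fiducial multiplier switches from the normal to the t quantile on
the residual df. LC_q = 10^((Φ⁻¹(q) − α)/β); its 95% fiducial limits solve
Fieller's quadratic for the ratio (Φ⁻¹(q) − α)/β, erroring when g ≥ 1 (slope
too imprecise for finite limits). Calibration: over 1000 simulated assays
(5 doses × 4 replicates × 25 larvae) the limits cover the true LC50 at 0.959.

Resistance ratios are RR_q = LC_q(population)/LC_q(reference). The CI takes
the widest ratio of bounds (lower/upper, upper/lower) — the conservative
reading of dividing "extreme" CI values; the implementation keeps this as
the only behaviour because under it the CI excludes 1 exactly when the
fiducial intervals are disjoint, making the published dual rule (disjoint
intervals AND CI > 1) internally consistent. A ratio is flagged significant
only under that dual rule.

## Association mapping

Population structure covariates are the top three principal components of
the SNP correlation matrix (columns standardized, missing dosages
mean-imputed for the PCA only; deterministic sign convention). Each marker
is tested in the least-squares model phenotype ~ intercept + PC1..PC3 +
dosage, with individuals missing that genotype dropped case-wise; marker R²
is the partial (RSS_reduced − RSS_full)/TSS and p comes from the partial F
test. Markers collinear with the covariates get p = 1 with a warning.

Multiplicity is handled by min-p permutation (B = 1000 by default): the
phenotype vector is permuted across individuals, all markers refit (via the
Frisch–Waugh reduction, so each marker costs one matrix product per batch of
permutations), and adjusted p_j = (#{min-p_b ≤ p_j} + 1)/(B + 1).

**Known limitation.** Each individual inherits its population's phenotype
(an LC95 measured per population), so the effective replication for
phenotype–genotype association is the number of populations. With six demes,
the intercept plus three PCs leave up to two axes of between-population
variation uncaptured; markers differentiated along those axes can reach
significance without being causal, and the permutation null (which destroys
all structure) does not protect against this confounding. Conversely the
same geometry caps power: simulations at the study design (6 demes × 30
individuals, Balding–Nichols F = 0.1) show power ≈ 0.15 for causal effects
worth two phenotype-noise SDs, rising above 0.5 only with twice as many
demes. The min-p correction itself is exactly calibrated: under an
exchangeable null (individual-level phenotype noise) the family-wise error
rate over 500 simulated panels is 0.05. Results from this module are
therefore best read as candidate rankings, not confirmatory tests — which is
how the original study treated them, following up candidates by sequencing.

## Concordance validation

Array QC keeps SNPs with GC50 > 0.35, GenTrain > 0.50 and call rate > 0.50
(strict inequalities). For SNPs under 10% missing data, pooled read-count
frequencies are compared with individual dosage frequencies (dosages
re-oriented to the pooled minor allele when the counted alleles differ):
Pearson's r across SNPs, plus a per-SNP Fisher exact test of pooled reads
against the 2N individual allele counts, Bonferroni-corrected by the number
of SNPs tested. `validation_summary` recomputes the headline percentages
from integer counts (genotyping success, laboratory validation,
transferability, natural-panel polymorphism, overall validation); with the
counts 372 arrayed / 353 genotyped / 13 monomorphic (10 recovered) / 324
transferred it reproduces 94.9 / 96.3 / 87.1 / 99.2%. The overall figure
uses the arrayed count as denominator; the genotyped-count variant can be
recomputed from the same integers.

## Synthetic data: what it does and does not establish

* **Pooled experiment**: per SNP, an ancestral frequency (uniform on
  0.05–0.95) drifts through `t = 20` generations of binomial Wright–Fisher
  sampling at Ne = 6000 in two descendant strains; selected loci (1% by
  default) get a deterministic genic-selection update (s = 0.5) each
  generation in strain 2 before sampling. Read counts are binomial at
  negative-binomial coverage (mean 100, dispersion 5, floored at 10) —
  overdispersed, as real pooled coverage is. The drift variance matches the
  closed form E[(p₁−p₂)²/2] = p₀(1−p₀)(1−(1−1/2Ne)^t) and selected loci
  stochastically dominate neutral differentiation.
* **Genotype panel**: Balding–Nichols island model (population frequencies
  Beta-distributed around the ancestral frequency with variance
  F·p(1−p), F = 0.1), six populations × 30 individuals, genotypes binomial;
  population phenotype = baseline + Σ effect·(causal population frequency) +
  population-level Gaussian noise; optional individual-level noise provides
  the exchangeable null used to calibrate the permutation correction. QC
  scores are drawn so ~5% of SNPs fail the array thresholds.
* **Bioassays**: deaths are binomial with mortality c + (1−c)·Φ(slope·
  (log₁₀ dose − log₁₀ LC50)) — exactly the model the probit module fits, so
  recovery tests are consistency checks of the estimator, not evidence about
  model mis-specification on real assays.

None of the generators include linkage between SNPs, expression-driven
biases of mRNA-derived allele frequencies, alternative splicing, or
genotyping error; passing tests therefore validate the statistical machinery
under its own assumptions, not robustness to those artefacts.

## Problem sizes used in the automated checks

The test suite simulates 10⁴ coalescent replicates for the E[S] check, 5000
for neutrality-statistic calibration, 1000 bioassays for fiducial coverage,
500 panels (B = 200 permutations) for FWER and 100 for power, and one
1520-SNP pooled experiment for the end-to-end scan — sizes chosen so the
whole suite completes in a few minutes while keeping Monte-Carlo error well
inside the asserted tolerances.
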