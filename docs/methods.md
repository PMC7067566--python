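# Methods

`pgsdesign` is a synthetic-cohort workbench for two questions about
polygenic scores (PGS) within a single ancestry group: why does prediction
accuracy differ across strata of the same cohort (sex, age, SES-like
groups), and how does a sibling-based PGS compare with a standard one when
both are given the same statistical precision? Every analysis runs end to
end on data from the package's own generator, so all claims the tests make
are claims about this generative model, stated below.

## Generative model

**Genotypes.** Biallelic SNPs are laid out in contiguous LD blocks.
A haplotype is a first-order copying chain within each block: the allele
at a SNP is copied from the previous SNP with probability *r*
(`within_block_r`, default 0.8) and drawn fresh Bernoulli(maf) otherwise;
blocks are independent. All SNPs of a block share one MAF (drawn uniformly
from `[maf_low, maf_high]`, default [0.05, 0.5]); this keeps the marginal
frequency of every SNP exactly at its panel MAF, which a copying chain
with heterogeneous MAFs would not. Adjacent-SNP haplotype correlation is
~*r* and decays geometrically with distance inside a block. Blocks are
separated by 2 Mb by default so a 1 Mb clumping window never spans blocks;
shrink `between_block_gap_bp` to make blocks interact with the window.

**Families.** Parents are simulated as unrelated individuals; couples are
formed either at random or by noisy rank-matching on the parental
phenotype (below); each parent transmits, independently per LD block, one
of its two within-block haplotypes intact — free recombination between
blocks, none within. Mendelian consistency is exact by construction and
asserted in tests. Two offspring per family; exactly one sibling pair is
retained per family, and "unrelated" cohort members are one offspring per
family so that everyone in a comparison has the same generative history
(this matters once indirect effects or assortative mating are on).

**Effects and trait.** A causal subset of `m_causal` SNPs receives direct
effects beta ~ N(0, h2/m_causal). The trait is

    y = a_s * sqrt(h2) * z_g + eta * z_ind + e_s * sqrt(1 - h2) * z_eps

with z_g the standardized additive genetic score (sum of allele counts
weighted by beta), z_eps standardized Gaussian noise, z_ind the
standardized sum of the two parents' *indirect* genetic scores, and
a_s / e_s per-stratum amplification and environment multipliers. With unit
multipliers and eta = 0, y has mean 0, variance 1 and corr^2(y, g) = h2
exactly in expectation. Optional additive sex and age terms (defaults 0 in
the generator; 0.2 / 0.1 in the experiment configs so covariate adjustment
has something to do) sit on top.

**Indirect effects.** Each causal SNP also carries an indirect effect;
the indirect vector is constructed to have an exact sample correlation
`rho_di` with the direct effects and standard deviation `indirect_scale`
times that of the direct effects. The phenotype receives the parents'
summed indirect score with weight eta (`indirect_weight`). This is a
"genetic nurture" pathway: a standard GWAS sees it (children's genotypes
are correlated with parental genotypes), a sibling-difference GWAS does
not (parental genotype is shared within a pair).

**Assortative mating.** Couples are rank-matched on phenotype after
adding Gaussian noise. With noise variance s·Var(y) per side the matched
spousal correlation is ~1/(1+s), so s = 1/r − 1 is the closed-form start;
one calibration iteration against the realized correlation refines it.
The procedure is deterministic given the seed and hits the target within
Monte-Carlo noise (tested at ±0.05 for r = 0.3).

**Strata.** Assignment is either random with configurable weights
(sex/age analogue) or by quantile-thresholding a collider variable
correlated with the baseline phenotype (SES analogue, emulating range
restriction). Amplification multiplies the genetic component; env_scale
multiplies the noise component.

**Binary traits** are made by strict thresholding of y at a value or
quantile (e.g. the 80th percentile for a hypertension-style definition).

## Association testing

`ols_gwas` computes, per SNP, the regression y ~ intercept + SNP +
covariates via exact Frisch–Waugh–Lovell residualization, with classical
SEs on n − n_cov − 2 degrees of freedom and two-sided t p-values — the
numbers are identical (tested to 1e-8) to the full multiple regression.
`logistic_gwas` fits per-SNP maximum-likelihood logistic regressions
(statsmodels); effects are log odds ratios with Wald SEs.
`sib_diff_gwas` residualizes the phenotype on age and sex over all
siblings, then regresses within-pair residual differences on within-pair
genotype differences, with intercept; n is the number of pairs.
Differencing removes everything shared within a family — parental
genotypes, family environment, and the between-family allelic correlations
induced by assortative mating — which is exactly why its effect estimates
diverge from the standard design's under those models.

Monomorphic SNPs (or sib pairs with no genotype differences anywhere, or
perfectly separated SNPs in the logistic path) are excluded with a logged
count, never emitted as NaN rows. Classical analytic SEs are used
throughout; a permutation-based empirical SE would be interchangeable here
but is slower and non-deterministic.

## Polygenic scores

Clumping is the greedy index-SNP algorithm: among SNPs at p ≤ threshold,
repeatedly take the most significant remaining SNP and drop all candidates
within ±1 Mb on the same chromosome whose genotype r² with it (computed in
a designated LD-reference sample of unrelateds) is ≥ 0.1. Ties in p break
by (chrom, pos). The default threshold grid is 1e-8 … 1e-2 in decades.
Scores are sums of weighted effect-allele counts (sum vs. average is an
affine choice that cannot move R² or AUC); allele mismatches against the
panel are auto-flipped with a log message when the stored other-allele
matches, and an error otherwise.

## Evaluation metrics

*Incremental R²* is unadjusted in-sample R²(covariates + score) −
R²(covariates); nonnegative by construction and invariant to affine maps
of score or covariates. *Incremental AUC* uses logistic fits for the two
models and computes AUC by the rank statistic with ties counted ½ (equal
to the trapezoidal ROC area; cross-checked against scikit-learn).
Distribution comparisons across resampling iterations use the two-sided
Mann–Whitney test (normal approximation with tie correction).

*Per-stratum adjusted variance* is the variance of the pooled-covariate
residuals within each stratum, with a fourth-moment standard error.

*SNP heritability* uses Haseman–Elston regression: products of
standardized residualized phenotypes regressed (with intercept) on
off-diagonal GRM entries. The slope and a delete-one-individual jackknife
SE are computed in closed form through trace identities (the n×n GRM is
never materialized), at O(n·m²) cost. The jackknife holds the full-sample
standardizations fixed, a standard approximation. With `snps="all"` the
estimator insists on an unlinked panel; on blocked panels it accepts an
explicit SNP subset (in practice the simulator's causal set), because with
LD and per-SNP standardization the moment condition holds only
approximately — per-stratum comparisons remain valid since any residual
distortion is shared across strata.

*Inverse-proportionality fit*: if strata differ only in environmental
variance then h2_s = Vg / var_s, so h² regressed through the origin on
1/variance should fit within estimator noise; amplification (genetic
variance varying) breaks the fit. Both the through-origin and
free-intercept variants are available.

## Study harnesses

**Stratified experiment.** Per iteration: equal-sized prediction sets are
held out per stratum; per-stratum GWAS sets are down-sampled to the
minimum stratum size q (rounded to a multiple of the stratum count), and a
"diverse" set of the same total size q takes q/S individuals per stratum;
an optional pooled set of size q·S mirrors the merged-GWAS check. Each
GWAS is clumped and thresholded at a single configured p (default 1e-3)
and evaluated by incremental R² (or incremental AUC for binarized traits)
in every prediction stratum. Per-stratum HE heritability and adjusted
variance are attached. Effect re-estimation ascertains SNPs in a pooled
GWAS disjoint from the prediction sets, re-estimates them within each
prediction stratum with effects oriented trait-increasing by the discovery
sign, and reports the cross-stratum regression slope with an
errors-in-variables correction (the predictor stratum's sampling variance,
mean se², is subtracted from its observed effect variance) — without this
correction regression dilution biases the slope toward zero at desk-scale
sample sizes — plus a delete-one-SNP jackknife SE.

**Sib-vs-standard comparison.** Per iteration: (1) a sibling set of
`n_sib_families` pairs is resampled from a larger simulated family pool
and the sibling-difference GWAS run on it — resampling keeps sib-GWAS
sampling noise iteration-specific, so across-iteration dispersion honestly
reflects all noise sources instead of conditioning every iteration on one
shared sibling draw; (2) n* estimation — standard GWAS on random
subsamples over a size grid, 1/median-SE regressed on sqrt(n) (the
relationship is linear to corr ≥ 0.99), inverted at the sib design's
median SE; the grid median is taken over a fixed random 500-SNP subset by
default (the same subset on the sib side) purely for speed; (3) an
n*-sized estimation set is removed from the unrelated pool and the rest is
split 10% prediction / 90% discovery; (4) the discovery GWAS is clumped at
each grid threshold; (5) ascertained SNPs get standard-design effects from
the estimation set and sib-design effects from the sibling GWAS; (6) both
scores are evaluated on the identical SNP list and identical prediction
individuals. Discovery, estimation and prediction sets are asserted
disjoint every iteration; sibs are distinct families from the unrelated
pool by construction. Matching median SEs equalizes expected prediction
accuracy under the vanilla model, which is the null the comparisons lean
on: parental indirect effects positively correlated with direct effects,
or positive assortative mating, each depress the sib/standard accuracy
ratio below 1 because the sib design removes predictive signal that is
real in the (equally structured) prediction cohort.

## Problem sizes and defaults

Desk-scale defaults: m = 2,000 SNPs in blocks of 10, m_causal = 500,
h2 = 0.5, 30,000 unrelateds, 4,000 sibling families, n*-grid 1,000–8,000
in steps of 500, LD reference 5,000, 10 iterations (30 for the vanilla
sib-vs-standard validation, 20 for stratified runs). These keep full runs
in the minutes range while preserving the contrasts of interest; absolute
accuracies are not comparable to biobank-scale analyses, only the
ratios and orderings the harnesses are built to measure. The indirect-
effect demonstration uses indirect_scale = 1, rho_di = 0.8, eta = 0.35
(an indirect pathway weaker than the direct one, in line with
genetic-nurture findings for behavioural traits); the assortative-mating
demonstration uses a spousal phenotype correlation of 0.4.

## What the generator does not emulate

Real LD (long-range structure, MAF-dependent LD), population structure
and its confounding (no PCs are simulated or needed), imputation dosages
(hard calls only), X chromosome, more than two siblings per family,
ascertainment into the cohort, and measured-covariate complexity. Passing
tests therefore demonstrate internal consistency of the designs and
estimators under a clean additive model — not robustness to the
confounders these designs face on real data. One generation of assortative
mating is simulated (parents mate, offspring are scored), so
equilibrium-AM predictions are only qualitatively reproduced.

## Numerical choices

Seeds are mandatory and all randomness flows from `numpy`'s SeedSequence
spawning, so identical configs are bit-reproducible including every
subsampling step. Regressions use float64 with QR-based residualization;
oracle agreement is tested at 1e-8 (regressions) and 1e-12 (scores).
Degenerate inputs error early: rank-deficient covariates, single-class
binary outcomes, constant phenotypes, strata smaller than 2, empty
Mann-Whitney samples. Empty clumping candidate sets return an empty
selection (and score models score everyone 0); thresholds with no
ascertained SNPs are reported as missing cells, never zero-filled.
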