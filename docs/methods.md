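# Methods

`bmiphenet` reimplements, on fully synthetic cohorts, the analysis chain
that links common genetic variation to body mass index (BMI) and onward to
the disease phenome: GWAS on transformed residuals, fixed-effects
meta-analysis and LD clumping, a weighted genetic risk score (GRS),
phenome-wide logistic association, one-sample and two-sample Mendelian
randomization (MR), and a φ-correlation disease comorbidity network with
community detection. This note documents the generative model, the
statistical procedures, the numerical choices, and what the synthetic
validation does and does not establish.

## The synthetic cohort generator

The generator's job is to emit data with the statistical structure the
analysis assumes, so that every stage can be validated by parameter
recovery rather than against inaccessible individual-level biobank data.

**Genotypes.** Each variant's effect-allele frequency is drawn uniformly
from `maf_range` (default 0.05–0.5). A dosage is the sum of two allele
draws (Hardy–Weinberg). Within blocks of `ld_block_size` consecutive
variants (default 10) the allele draws share a latent equicorrelated
Gaussian with correlation `ld_rho` — a Gaussian copula on the haplotype
level. This is the simplest LD model that makes r²-based clumping
non-trivial: dosage correlation is high within blocks and zero between
them. It does not reproduce the long-range, distance-decaying LD of real
genomes.

**Covariates.** Age is normal (mean 63.95, SD 13.11 years, clipped to
19–104), sex is Bernoulli with male fraction 0.93, and the ten principal
components are independent standard normals centered to zero — the
demographic profile of a large, predominantly male veteran biobank. PCs
are consumed as covariates; the package never computes them from
genotypes.

**BMI.** On a standardized (unit-variance, covariate-free) scale,
`z = g + c + κU + e`: `g` is the additive genetic value over `n_causal`
variants with normal effect sizes rescaled so its realized variance equals
`h2_bmi` exactly (default 0.188); `c` adds configurable covariate effects
(defaults: −0.10 SD per SD of age, +0.10 SD for male sex — modest,
realistic shifts); `U` is an optional unmeasured standard-normal
confounder with coefficient κ (`confounder_bmi_effect`, default 0); and
`e` is Gaussian with variance `1 − h2_bmi − κ²`. The trait is placed on
the kg/m² scale as `bmi_mean + bmi_sd·z` (defaults 29.88 and 5.86).

**Phecodes.** Disease status is Bernoulli given a logistic linear
predictor:

    logit P(case) = logit(prev) + γ·BMI_std + λ·F_block + δ·U + covariate terms

where γ is the causal log-odds ratio per SD of BMI, `F_block` is one
standard-normal factor per individual shared by all codes of the same
community block (the mechanism that makes diseases co-occur beyond their
shared BMI dependence), and δ couples the code to the unmeasured
confounder. Statuses are conditionally independent given the linear
predictor; there are no exclusion ranges or missing states. The default
12-code panel uses per-SD odds ratios in the range reported by phenome-wide
BMI studies (T2DM 2.64, sleep apnea 2.36, hypertension 2.20, down to
protective inguinal hernia 0.58) and block loadings of 1.2, which place
within-block φ-correlations at roughly 0.2–0.3 — the regime in which a
comorbidity network with the standard φ ≥ 0.2 edge threshold has
structure. The block-latent-factor form is an assumption of this
simulator; real comorbidity arises from mechanisms no low-dimensional
factor model fully captures.

**Two-sample summary statistics.** True exposure effects are half-normal
(SD 0.05 plus a 0.01 floor so every instrument is relevant); observed
exposure and outcome betas add Gaussian noise at stated SEs (defaults
0.005 and 0.02). The outcome beta is `β_causal·β_X + α_j + noise` with the
direct (pleiotropic) effect `α_j` zero for valid instruments, mean-zero
normal under balanced pleiotropy, and a constant `pleiotropy_delta` for a
`frac_invalid` fraction under directional pleiotropy. Because the invalid
subset is chosen independently of instrument strength, the InSIDE
condition holds and the Egger intercept estimand is the mean direct effect
`frac_invalid · delta`.

**Reproducibility.** All draws come from named substreams
(`SeedSequence([seed, crc32(name)])`) of one master seed: identical
config + seed gives bit-identical output, and adding a phecode to the
panel does not perturb the genotype or BMI draws.

## Association chain

**Residualization and transform.** BMI is residualized within each sex
stratum on age, age², and pc1–pc10 by OLS; the pooled residuals are mapped
to normal scores by the rank-based inverse normal (Blom) transform,
`Φ⁻¹((r − 3/8)/(n + 1/4))` with average ranks for ties. Whether the
transform should be applied within strata or pooled is not dictated by the
two-step recipe itself; pooled is the default and per-stratum is a
one-line variant (transform each stratum's residuals separately).

**GWAS.** Each variant is tested by closed-form simple linear regression
of the transformed residuals on dosage (covariates were consumed by the
residualization, so none enter here). P-values use the normal
approximation by default — at the intended sample sizes the t and normal
references are indistinguishable — with an exact-t switch for n < 100.
Monomorphic variants have no defined SE and are skipped with a logged
count. The genomic-control λ (median χ² / 0.4549) is provided as the
standard inflation diagnostic; under polygenic architecture it exceeds 1
even without confounding, which the demo analysis reproduces.

**Meta-analysis.** Fixed-effects inverse-variance weighting; records are
matched by variant id and harmonized to the first-seen allele pair (an
exact effect/other swap flips the sign and frequency; anything else is
dropped with a logged reason). Strand-ambiguous pairs are not given
special treatment because the simulator controls strand.

**Clumping and loci.** Significant variants (p < 5×10⁻⁸) are accepted
greedily in ascending-p order (ties: chromosome, then position) if their
squared Pearson dosage correlation with every previously accepted variant
is < 0.1. Accepted variants chained within 500 kb on one chromosome form a
locus; the smallest-p member leads. A locus is novel if its lead is more
than 500 kb from every catalog variant on the same chromosome and, when a
dosage panel for the catalog is supplied, in LD r² < 0.1 with each of
them. Coordinates are 1-based and distance checks inclusive, so 500,001 bp
is novel and 500,000 bp is not.

## Genetic risk score

The GRS is `Σ w_j · dosage_j` over the independent genome-wide-significant
SNPs, with weights taken from an external association source aligned to
each SNP's effect allele (a mismatched effect allele counts the complement
`2 − dosage`). External weights avoid winner's-curse overfitting when the
score instruments the discovery cohort itself. Dosages are not
frequency-centered: affine shifts change no downstream association.
"Variance explained" is the incremental R² over the covariate model by
default, with plain univariate R² behind a flag, since either convention
is common and they differ when covariates explain trait variance.

## Phenome-wide association and Mendelian randomization

Codes with at least 200 cases and 200 controls (inclusive) are tested.
The observational PheWAS is a per-code maximum-likelihood logistic
regression of status on standardized BMI plus age, sex, and pc1–pc10;
non-convergence or separation flags the code rather than failing the scan,
and flagged codes are excluded from significance counts. Significance is
Bonferroni over the number of codes tested (0.05/1244 = 4.02×10⁻⁵ and
0.05/833 = 6.00×10⁻⁵ at the catalog sizes of a phenome-wide study).

**One-sample MR.** Stage 1 regresses standardized BMI on the GRS plus
covariates (coefficient b_X); stage 2 is a logistic regression of each
code on the same design (coefficient b_Y); the estimate is b_Y/b_X — the
log-OR per SD of BMI — with first-order delta SE `se_Y/|b_X|`. The first
stage is treated as precisely estimated; with a first-stage F in the
hundreds its noise is negligible next to se_Y, and a first-stage t < 10
attaches a weak-instrument warning. Two estimands are available:

* **ratio** (default): stage 2 marginalizes over the BMI variance the
  score does not explain, so it targets a population-averaged OR that the
  non-collapsibility of the odds ratio attenuates relative to the
  conditional effect — about 6% on the log scale at h² = 0.2 and γ =
  log 2, as the standard approximation √(1 + 0.346·γ²·(1−R²)) predicts.
* **2sri** (two-stage residual inclusion): the first-stage residual enters
  stage 2 as a covariate, making the logistic model correctly specified
  under the generative liability chain, so the estimator targets the
  conditional log-OR. Recovery tests that compare against the generative γ
  use this estimator; at the study conditions its 95% CI covers the
  generative OR in ~95% of replicates with calibrated SEs.

**Two-sample estimators.** IVW is the inverse-variance-weighted slope
through the origin (fixed-effect SE; a multiplicative random-effects
inflation is available). Egger regression is WLS of outcome on exposure
betas with a free intercept after jointly flipping pairs so all exposure
betas are non-negative; the intercept estimates directional pleiotropy and
inference uses the t reference with m−2 df. The weighted median orders the
Wald ratios, weights them by inverse delta-method variance, and
interpolates the 50% point of the cumulative midpoint weights; its SE
comes from a parametric bootstrap (default 1,000 draws, seed mandatory).
With three equal-weight ratios the cumulative midpoint weights hit 0.5
exactly at the middle ratio, so {1, 2, 9} → 2.

**Burden.** Per individual, the number of MR-associated codes with case
status, summarized by BMI category (<25, 25–30, 30–40, ≥40 kg/m²; lower
bounds inclusive, so BMI exactly 30 is obese) with a linear-regression
trend test of burden on the ordinal category index.

## Comorbidity network

MR-associated dotted codes are rolled up to their integer-part (3-digit)
parents — an individual is a case for the parent if a case for any child —
and every unordered pair is scored by the φ-correlation

    φ_ij = (C_ij·N − P_i·P_j) / sqrt(P_i·P_j·(N − P_i)·(N − P_j)),

Pearson's correlation for binary indicators, computed over the full cohort
(every individual contributes a 0/1 observation per disease). Significance
uses t = φ·√((N−2)/(1−φ²)) with N−2 df — the standard test of a Pearson
correlation — adjusted across all tested pairs by Benjamini–Hochberg
(chosen because "adjusted p-value" is the language of FDR control;
Bonferroni is a flag). Edges are retained at adjusted p < 0.05 and
φ ≥ 0.2 (inclusive); isolated nodes are dropped from the rendered network
by default.

Communities come from Louvain modularity maximization on the unweighted
retained-edge graph (φ-weighted variant by flag), deterministic under a
seed, with labels assigned by descending community size. Community
significance is a permutation test: each of `n_null` replicates rewires
the graph by degree-preserving double edge swaps, re-partitions it with
Louvain, and contributes the modularity quality (l_c/m − (d_c/2m)²) of the
size-nearest null community; p = (1 + #{null ≥ observed})/(1 + n_null),
judged against Bonferroni over the number of detected communities
(0.05/12 ≈ 0.0041 when twelve are found). This rewiring null approximates
the published community-significance test whose exact statistic has
unstated tunables; on Erdős–Rényi control graphs it fires at or below the
nominal rate, and it is exactly conservative for communities that the
degree sequence alone reproduces (a lone clique rewires to itself and gets
p = 1).

## Problem sizes and what the validation shows

The validation suite runs at deliberately desk-scale sizes: two-sample
estimator recovery uses 100 instruments × 500 replicates; one-sample MR
uses n = 20,000 cohorts with a 200-variant causal architecture at h² = 0.2
(100 replicates for coverage, 100 for the confounding contrast); the null
GWAS uses 10,000 variants; the planted network uses two blocks of eight
codes in n = 4,000 with 200 rewiring nulls. These sizes make every check
reproducible in minutes on one CPU while keeping Monte-Carlo error small
enough for the stated tolerances.

Passing these checks establishes that the estimators recover the
parameters of their own generative model at realistic effect sizes, that
the observational/causal contrast behaves correctly under unmeasured
confounding, and that the network pipeline recovers planted co-occurrence
structure with a calibrated null. It does not establish robustness to the
many features of real biobank data the generator omits: distance-decaying
LD and allele-frequency/effect-size coupling, population stratification,
phecode exclusion ranges and misclassification, informative missingness,
relatedness, or selection into the cohort.

## Known limitations

* The LD model is block-equicorrelated; clumping behavior on real panels
  (long-range LD, MHC) is not represented.
* The ratio MR estimator reports a population-averaged OR; users comparing
  against liability-scale effects should use the 2SRI flag.
* The weighted-median bootstrap resamples betas parametrically at their
  stated SEs; it does not propagate weight re-estimation uncertainty
  beyond that.
* qstest-style community significance is approximated by the rewiring
  null described above, with the comparison community matched on size
  only.
* Heritability enters as the target variance fraction of the additive
  genetic value; no LD-score-based estimation is provided or claimed.
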