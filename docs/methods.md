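# Methods

## The setting

An inbred-line panel screen challenges replicate vials of flies from each
of ~185 near-fully homozygous lines with a pathogen and records either
per-fly survival time (checked every 24 h) or an infected/uninfected count
per vial. Susceptibility differences between lines are genetic;
differences between vials of the same line are micro-environmental; the
remainder is residual. Because every line is homozygous, each line carries
one allele per site and the between-line genetic variance is twice the
additive variance of the randomly-mating base population — hence
V_g = V_line/2 everywhere in this package.

## Variance-component models

**Gaussian nested model** (survival): y_ijk = β + b_i + c_j + ε_ijk with
independent normal line, vial and residual terms. Fitted by conjugate
Gibbs sampling — every full conditional (effects: normal; variances:
inverse-gamma) is available in closed form, so the sampler is exact and
fast.

**Binomial logit model** (infection counts): the infected count of a vial
is binomial with logit(p) = β + b_i + ε_ij, the vial-level normal ε
absorbing extra-binomial (overdispersion) variance. No conjugate update
exists for the effects under the logit link, so the sampler uses
coordinate random-walk Metropolis within Gibbs: all line effects are
proposed and accepted in parallel (they are conditionally independent
blocks), likewise all vial deviations, while the two variances keep
conjugate inverse-gamma updates. Proposal scales adapt during burn-in
toward ~44% acceptance (the one-dimensional optimum) with a diminishing
adaptation step, then freeze, preserving the stationary law.

**Multivariate binary model** (genetic correlations): all traits are
reduced to per-vial counts — survival traits are binarized as dead/alive
at a single day, by default the observation day at which pooled mortality
is nearest 50% (the day maximizing the information in a binary split; any
day can be forced). Each line carries a vector of effects across traits,
multivariate normal with covariance Σ; Σ gets a conjugate inverse-Wishart
update and each trait its own overdispersion variance. Line-effect columns
are updated one trait at a time against their conditional prior from the
current Σ. The genetic correlation r = Σ_ij/√(Σ_ii Σ_jj) is computed per
draw; its MCMC p-value is 2·min(P(r>0), P(r<0)) over draws, floored at
1/n_draws so a degenerate posterior reports the smallest resolvable value
rather than zero.

### Priors, chain lengths, summaries

- Variance priors default to inverse-gamma(0.01, 0.01) — proper but
  weakly informative. A flat scale prior p(σ²) ∝ 1/σ² is available behind
  `improper=True`; with few levels it can produce an improper posterior,
  which is why it is not the default. The multivariate model uses
  inverse-Wishart(T+1, 0.1·I), whose implied marginal prior on each
  correlation is uniform.
- Grand means take flat priors.
- Defaults are 20,000 iterations per chain, 5,000 burn-in, thinning 10,
  two chains. Effective sample size and split scale-reduction are reported
  per component via ArviZ. The test suite uses shorter chains (3,000–6,000)
  — parameter-recovery checks need far fewer draws than publication-grade
  interval estimates.
- Point summaries are posterior means with 95% highest-posterior-density
  intervals. Nonlinear transforms (h², correlations, CV_g) are computed per
  draw and then summarized — a ratio of posterior means is *not* the
  posterior mean of the ratio, and the package never conflates the two.
  (Consequence worth knowing: plugging published component means into the
  h² formula reproduces published h² only to ~0.01, exactly because of
  this nonlinearity.)

### Moments oracle

`moments_nested_anova` implements the expected-mean-squares solution of
the two-level nested design with unbalanced group sizes (Sokal–Rohlf
coefficients), truncating negative solutions at zero with a flag. It is
deterministic, assumption-light, and serves as an independent check on the
Gibbs sampler: on balanced designs of ≥200 lines the two agree within a
few percent.

### Degenerate designs

One vial per line everywhere makes V_vial inestimable: it is fixed at 0
with a warning (Gaussian model) or flagged (moments). A single line has no
between-line contrast and is rejected. All-zero or all-n infected counts
leave β weakly identified; the fit warns and proceeds.

## GWAS

Line values are the fly-count-weighted mean survival (equivalently the
plain mean over flies), or the pooled proportion infected with an optional
arcsine-square-root variance-stabilizing transform (per-trait
configurable). Genotypes are coded −1/+1 for the two homozygote classes so
the regression slope is a, half the homozygote difference; swapping allele
labels flips the slope's sign and nothing else. Sites must be biallelic
with the minor allele in at least 4 lines after within-line segregating
calls are set missing. Missing genotypes are dropped casewise per site;
joint multi-SNP fits use listwise deletion. The regression is unweighted
across line values (the fly weighting already acted when forming the line
mean); a weighted variant is deliberately out of the default path.

The genome-wide threshold permutes the phenotype vector across lines,
rescans the full genome, records the minimum p, and takes the empirical
α-quantile (linear/type-7 interpolation) of those minima over 400
permutations. Covariate genotypes stay attached to their lines — only the
phenotype is shuffled — so the conditional scan's null preserves the
covariate structure. QQ expectations pair the k-th observed order
statistic with the mean k-th order statistic across the stored permutation
scans.

Joint fits compute each site's marginal F-test (full model vs the model
dropping that site); sequential fits add sites in a stated order,
ANOVA-style, testing each increment against the full-model residual.
Rank-deficient designs report aliasing instead of p-values. These tests
are plain nested-model least squares built on `numpy.linalg.lstsq`; the
test suite cross-checks them against statsmodels OLS.

No kinship/mixed-model correction for population structure is applied —
the line-panel design this targets used none, and an inflated QQ tail may
partly reflect uncorrected stratification; interpret borderline hits
accordingly.

## Variance explained and dominance projection

The slope's square overestimates a²; the package uses the unbiased
â² − SE(â)², floored at zero (flagged) when noise dominates. A locus
contributes 2pqa² of additive variance; frequencies are computed over
genotyped lines only, and the resistant allele is oriented by the sign of
â relative to the trait's polarity (higher survival = resistant; lower
infection = resistant). Summing contributions across loci assumes linkage
equilibrium between them; the package checks pairwise genotype r² and
warns when contributions overlap.

Homozygous panels cannot see dominance, so extrapolating a locus's share
of V_a to an outcrossed population requires an assumption. With dominance
deviation d = d_ratio·a, the average effect is α = a + d(q−p) and the
locus's outbred additive variance is 2pqα² = 2pqa²(1 + d_ratio(q−p))².
The share reported is locus V_a over locus V_a plus
frac_remaining_additive·(V_g − 2pqa²). Dominance variance (2pqd)² is
excluded from both numerator and denominator: the projection concerns
additive variance only. The closed form is verified against a brute-force
oracle that enumerates Hardy-Weinberg genotype frequencies and regresses
genotypic value on allele count (agreement to 1e−10). The two verbal
extremes — "resistant allele fully dominant" and "fully recessive" — are
exposed as d_ratio = +1 and −1 rather than as prose, because the two
phrasings are easy to confuse; together with the frequency of the
resistant allele among genotyped lines they reproduce the published 84%
and 7% projections for the major DCV-resistance locus.

## Synthetic data

The generator emulates what the analysis models assume, and only that:

- Minor-allele frequencies are drawn as Beta(a, b)/2 (default a = b = 0.7,
  a U-shaped folded-SFS-like law on (0, 0.5)).
- LD is a first-order Markov copy process: each site copies the previous
  site's line-assignment pattern with probability `ld_copy_prob` (default
  0.7), giving blocks of perfectly correlated sites and geometric r² decay
  with distance. This is the simplest process with tunable, monotone LD; it
  is *not* a coalescent and carries no recombination map, mutation model,
  demography or selection.
- Missing and within-line-segregating calls are overlaid independently at
  the stated rates (defaults 3% and 1%).
- Phenotypes are generated exactly under the fitted models: planted locus
  effects ±a on line values, normal polygenic line deviations, normal
  vial/overdispersion deviations, normal residuals or binomial counts.
  Defaults mirror the assay design: 4 vials per line, 15 flies per vial
  (the fly count per vial is a configurable guess — assay reports rarely
  state it).
- Survival values are continuous by default; 24-h day-rounding (with a
  floor at zero) is optional, since daily checks discretize real data.

Passing recovery tests on these data therefore demonstrates correctness of
the estimators under their own assumptions — not robustness to real-data
violations such as non-normal survival times, census-size variation,
block/day effects, cryptic relatedness between lines, or
frequency-dependent missingness.

A truth manifest (trait definition, causal loci, seeds, realized per-line
genetic values) accompanies every simulated phenotype table and
round-trips through a flat tab-separated text format.

## Numerical and design choices

- Genotype codes: hom-ref 0, hom-alt 2, missing −1, within-line
  segregating −2; the segregating code is distinct so the raw information
  survives, but every analysis maps it to missing.
- Coordinates are 1-based, chromosome-arm-named ("3L:7350895"); VCF input
  maps 0/0→0, 1/1→2, 0/1→segregating, any half-call→missing.
- Perfect-fit regressions (zero residual) report p at the smallest
  positive float rather than 0, keeping −log10 finite.
- Permutation engines and simulators take explicit integer seeds;
  identical seeds give byte-identical outputs, and every pipeline artifact
  records the seed and config hash that produced it.
- The binarization day for the multivariate model and the per-trait
  arcsine transform are the two places where an unstated upstream choice
  had to be made; both are explicit, defaulted, and overridable.
- Test problem sizes: recovery checks run at the panel scale the models
  target (150–200 lines, 2,000 sites for threshold calibration, 20
  replicates for coverage checks) with chains shortened to what those
  checks need. Interval-coverage checks for genetic correlations require
  the full design's information content: at 150 lines × 3 vials, chance
  cross-trait correlation of the vial noise is large enough that a correct
  95% interval excludes zero noticeably more than 5% of the time (verified
  against an independent glmmTMB fit of the same data); at 200 lines × 4
  vials coverage is nominal.

## Known limitations

- The binomial samplers are random-walk MH: adequate here, but slower
  mixing than specialized augmentation schemes for very large panels.
- No REML path for unbalanced multivariate designs; no pedigree or
  genomic-relationship matrices; logit is the only binomial link.
- No imputation, no indels, no haplotype fine-mapping, no sweep
  statistics, no stratification correction.
- The LD simulator cannot produce realistic long-range LD decay profiles
  or allele-frequency/LD coupling; use a coalescent simulator when those
  matter.
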