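# Methods

`clonepart` partitions the total genetic variance observed among clonally
replicated full-sib offspring into additive and non-additive components,
using genomic relationships on a genotyped subset of the offspring and
spatially modelled phenotypes on all of them.  This note records the models,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## The mixed models

For one trial (a site-by-family combination) the phenotypes of the observed
plots follow

    y = X b + Z_u u + Z_v v + e

with a fixed intercept (optionally a mean-centred individual-heterozygosity
covariate), a total genetic effect per offspring genotype `u`, replicate
block effects `v ~ N(0, sigma_v^2 I)`, and residuals

    e ~ N(0, R),   R = sigma_r^2 I + sigma_s^2 (+)_k AR1(rho_c) x AR1(rho_r)

where the separable AR1xAR1 spatial term is block-diagonal over master
blocks (spatially contiguous grid units), all master blocks of a trial
sharing the same `(sigma_s^2, rho_c, rho_r)`.  The nugget fraction is
`f_r = sigma_r^2 / (sigma_r^2 + sigma_s^2)`.

**Model 1** takes `u ~ N(0, sigma_u^2 I)` for all offspring: `sigma_u^2` is
the total (clonal) genetic variance, estimable because every genotype is
replicated as ramets across blocks.

**Model 2** splits the genotyped offspring's effect into an additive part
with covariance proportional to the VanRaden method-1 genomic relationship
matrix G and an independent non-additive remainder, while ungenotyped
offspring keep an unstructured total effect:

    var(u_1)     = sigma_u^2 I                (ungenotyped)
    var(u_2(a))  = sigma_u^2 r_a G / k        (genotyped, additive)
    var(u_2(d))  = sigma_u^2 (1 - r_a) I      (genotyped, non-additive)

Because the G-attached variance parameter refers to a Hardy-Weinberg
population rather than to the family at hand, the family's realized additive
variance is `k sigma_a^2` with `k = mean(diag G) - mean(G)`.  The
parameterization above encodes the constraint
`sigma_u^2 = k sigma_a^2 + sigma_d^2` *structurally*: `r_a` is the additive
fraction of the within-family total genetic variance and the constraint can
never be violated at any parameter value.  Within a pure full-sib family
`f_a = r_a` directly.

No attempt is made to split the non-additive remainder into dominance and
epistatic parts; with within-family data and ~10^3 markers that further
partition invites overfitting.

## G, k and allele frequencies

G = W W' / sum_i 2 p_i (1 - p_i) with W the dosages centred at 2 p_i.
Dosages are posterior-expected allele counts when genotype probabilities are
available, else hard calls.  For a verified full-sib family the centring
frequencies come from the two parents (0.25 / 0.5 / 0.75 for segregating
loci); for a family found to be a paternity mixture, observed offspring
frequencies are used.  Loci monomorphic in the family are excluded (they
carry no weight in method 1 either way).  Missing dosages are mean-imputed
at 2p and logged loudly - imputed probability input should not contain any.

A subtlety worth recording: with family-internal (parental-frequency)
centring, sib genotypes are conditionally independent given the parents, so
the *expected* off-diagonal of G is 0, not the textbook full-sib 0.5 (which
refers to population-frequency centring).  G here measures Mendelian-sampling
deviations: realized sharing of parental haplotypes.  Consequently
`k ~ mean(diag G)`, and its magnitude is set by the segregation-class mix:
het x het loci contribute var/2p(1-p) = 1, het x hom loci 2/3.  The default
generator mix (10% het x het) puts k near 0.70, the magnitude seen in RADseq
full-sib data; the tests assert k in [0.6, 0.8] at study scale.

## REML fitting

The REML log-likelihood (fixed effects profiled out, constant included) is
evaluated densely: V is assembled from precomputed structure matrices
(same-genotype and same-block indicators, the expanded `G/k - I` core, and
integer displacement tables driving power-lookup AR1 products), then
Cholesky-factorized.  An eigendecomposition evaluation path exists for
cross-checking; both agree with an independent brute-force implementation to
1e-8 in the tests.

Optimization works on transformed parameters - log variances,
atanh-transformed autocorrelations bounded to (-0.999, 0.999), logit r_a -
so the search is smooth and unconstrained and `r_d = 1 - r_a` is built in.
Steps are average-information (AI) Newton updates from analytic REML
gradients with step-halving and a trust region, typically converging in
10-20 iterations; a stalled run falls back to Nelder-Mead and re-polishes.
Three jittered multi-starts are the default guard against local optima
(profiles use one, warm-started).  Non-convergence is flagged on the
returned fit, never silently ignored.  Standard errors come from the
numerically differentiated observed information at the optimum
(delta-method back-transform); a cheaper AI-based approximation is always
attached and drives the profile grid placement.

Variances may hit the zero boundary (log-scale bound at e^-20); note that at
`rho ~ 0` the split between nugget and spatial variance is barely identified
- only their sum and the implied lag-1 covariance are - so boundary fits are
judged on those functions in the tests.

Missing phenotypes (fillers, controls, dead trees) are simply absent rows:
the observed-plot submatrix of R is used directly, so no filler phenotypes
are needed to keep grids continuous.  The dense path warns above 6000
observed plots per trial, the intended ceiling.

## Profiles, pooling and corrections

The additive fraction is profiled by re-maximizing all nuisance parameters
at fixed `r_a` over a grid in [0, 1] (21 coarse points plus 10 refinements
near the optimum by default; callers may supply a grid), warm-starting each
point from its nearest fitted neighbour.  The deviance
`D(r_a) = -2(logL(r_a) - max logL)` is normalized to minimum 0; the 95% CI
is `{r_a : D < 3.84}` with linear interpolation at the crossings, endpoints
clamped to 0/1 when the deviance never crosses on a side.  Non-convergent
grid points are flagged and interpolated over with a warning; non-unimodal
profiles return the widest enclosing interval with a warning.

Profiles from several trials are pooled by summation after monotone-cubic
re-interpolation onto a common 201-point grid; the consensus is the pooled
argmin, its CI uses the same 3.84 rule, and heterogeneity is
`X^2 = sum_i D_i(consensus)` on (number of profiles - 1) df.  Multi-site
composites are formed by summing per-site tests; scalar estimates (spatial
parameters, heritabilities) pool by inverse-variance weighting.

Heritabilities: `sigma_P^2 = sigma_u^2 + sigma_v^2 + sigma_r^2 + sigma_s^2`,
`H^2 = sigma_u^2 / sigma_P^2`, `h^2 = f_a H^2`.

**Half-sib-mixture correction.**  A "full-sib" family that is secretly a
q : (1-q) mixture of two maternal half-sib families contains extra
between-subfamily variance.  With population additive variance V_A and
dominance-type variance V_D, the within-full-sib shares are V_A/2 and
(3/4) V_D, and mixing adds `q(1-q)/2` of each population variance between
subfamilies (half-sib additive relationship 1/4, half-sib dominance
relationship 0, unrelated sires), giving shares

    c_A = 0.5/(0.5 + q(1-q)/2),   c_D = 0.75/(0.75 + q(1-q)/2).

Solving the odds relation `f_a/(1-f_a) = (c_A/c_D) r_a/(1-r_a)` and
normalizing the denominator constants to 3 and 2 yields, at q = 0.594,

    f_a = 2.81 r_a / (3 - 0.19 r_a),   f_d = 2.14 r_d / (2 + 0.14 r_d),

reduced exactly to the identity at q = 1.  A Monte-Carlo oracle (explicit
loci, explicit parents, measured within- vs mixture variances) verifies c_A
and c_D in the test suite.  Dominance-like covariance (FS 1/4, HS 0) is the
assumed non-additive structure; additive-by-additive epistasis is not
modelled separately.

**Random-mating conversion.**  Half of additive but three quarters of
dominance and additive-by-additive variance segregates within families, so a
within-family fraction f corresponds to `3f/(2+f)` in a random-mating
population; 0.6 and 0.8 map to 0.69 and 0.86.

## The synthetic-data generator

The generator emulates a three-site clonal progeny test of large full-sib
families: a 12-linkage-group map (~1630 evenly spaced SNPs, group lengths
128-218 cM), parents drawn by segregation class, gametes by the Haldane
model (Poisson crossovers at 1 per 100 cM, no interference - the simplest
standard model given that only map distances inform the analysis),
offspring as gamete sums, a genotyped subset per family, and per-call
missingness plus genotype-probability triples whose argmax errs at a set
rate (default 0.013).  One family can be a hidden q : (1-q) two-sire
mixture (default q = 0.594).

Genetic values: additive effects at causal loci sampled among the mapped
SNPs; non-additive values use the *within-family dominance deviation* - the
per-locus residual of heterozygosity on dosage.  At a locus with one
homozygous parent, heterozygosity is a linear function of dosage within the
family, so its within-family dominance deviation is zero and only
het x het loci contribute, exactly as quantitative-genetic theory requires;
coding raw heterozygosity instead would leak "dominance" into the additive
span and bias the recovered r_a towards 1.  The aggregate dominance vector
is then residualized against the additive vector and both are rescaled so
the realized decomposition hits `r_a sigma_u^2` and `(1-r_a) sigma_u^2`
exactly - the generator's truth is defined operationally, the way the model
measures it.

Field trials: each block is a column-by-row grid; blocks of a master block
stack into one continuous grid; every offspring gets one ramet per block at
a seeded-random plot; surplus plots are fillers with missing phenotypes
(standing in for un-cloned controls).  Spatial errors are exact separable
draws via the matrix-normal identity `sqrt(sigma_s^2) L_c Z L_r'` with L the
Cholesky factors of the AR1 correlations; block effects and nugget are
i.i.d. normal.  Default noise (sigma_v^2 = 0.1, sigma_r^2 = 2.0,
sigma_s^2 = 0.9, rho = 0.85 with sigma_u^2 = 1) gives H^2 = 0.25 and
f_r = 0.69, mid-range for juvenile growth traits in conifer trials.

What the generator does **not** emulate: sequence reads and their QC,
linkage-disequilibrium structure beyond within-family co-segregation,
genotyping-error correlation across loci or individuals, mortality,
inter-plot competition, non-Gaussian traits (bud-burst scores are ordinal in
reality), and selection.  Passing tests therefore demonstrate correctness of
the estimation machinery under the stated model, not robustness to every
field artefact.

## QC stage

Filters run sequentially - individuals with call rate < 0.6 first, then SNPs
with call rate < 0.8 or MAF < 0.15 computed from the retained offspring
("less than" is strict; equality is retained; parents are excluded from the
MAF, an offspring-QC context).  The Mendelian screen tests observed
offspring genotype counts against the cross's expectation, pooling expected
cells < 1 into the nearest class, removing SNPs at the Bonferroni-corrected
0.05 level over the SNPs actually tested.  Opposing homozygotes
(parent and offspring homozygous for different alleles) are counted per
offspring and the offending calls censored, parents being treated as
reliable.  Mixture detection thresholds the per-offspring incompatibility
rate at 3x the background genotype-error rate (default 0.013) and confirms
with a deterministic 1-d 2-means split; both must agree (95% identical
partition and cluster separation > 2x background) for a "mixture" verdict,
with "no mixture" and "ambiguous" as honest alternatives.  The reported
subfamily fraction carries its binomial standard error sqrt(p(1-p)/n).

The single-pass filter order means idempotence is a property of realistic
data (it holds throughout the simulated studies), not a theorem: removing
SNPs changes individual call rates, so adversarial matrices can lose further
individuals on a re-run.

## Problem sizes used in the test suite

Unit tests run on 50-200-offspring families over 120-400-SNP maps and
80-240-plot trials; the recovery suite runs 30 trials of 200 genotyped
offspring x 4 ramets (800 observed plots, full 1630-SNP map) at true
r_a = 0.75, checking mean-estimate error <= 0.05 and >= 85% profile-CI
coverage; the oracle-equivalence suite uses 50 random instances with n <= 40.
These sizes were chosen so the full suite exercises the study-condition
geometry (same ramet counts, grid shapes and marker density per family)
while remaining a routine desktop run.

## Known limitations

- The dense REML path is O(n^3) per evaluation; trials far beyond ~6000
  observed plots need a sparse or structured backend not provided here.
- r_a estimates from a single trial of this size carry standard errors near
  0.1; single-trial CIs routinely span half the unit interval.  Pooling
  across trials is the intended mode of use.
- Heterogeneity bookkeeping for multi-site composites sums per-site tests;
  other df conventions exist.
- The mixture correction assumes the non-additive variance is dominance-like
  (or additive-by-additive) in its family covariance; purely epistatic
  structures with different within-family shares would need other shares.
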