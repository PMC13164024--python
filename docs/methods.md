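# Methods

This note documents the statistical machinery, the synthetic cohort
generator, and the numerical choices behind `burdencif`. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Data model

The analysis dataset is one row per subject: age in years (onset for
affected subjects, last follow-up for presymptomatic carriers, who are
censored), an event code (0 censored, 1 AD, 2 FTD; or 0/1 for the
composite any-dementia endpoint), and a family identifier. The time
scale is age with no delayed entry: onset ages are modelled directly and
left truncation is not represented. Genotypes are dosage matrices
(0/1/2 minor-allele copies); missing calls are imputed to the variant's
observed mean for score computation and excluded pairwise for LD r²
(the imputed fraction is logged). Variant annotations carry a class
(`causative`, `VUS`, `non_causative`); only non-causative variants may
enter scores, and the weight table enforces this.

Region filtering treats BED intervals as 0-based half-open and
annotation positions as 1-based; an interval `[s, e)` with flank `f`
(default 5000 bp) retains 1-based positions `s − f + 1 … e + f`, with
the expanded start clamped at zero. Chromosome names are compared after
stripping a leading `chr`.

## Fine–Gray regression

`fit_fine_gray` maximizes the inverse-probability-of-censoring-weighted
(IPCW) partial likelihood of the subdistribution hazard. Subjects
failing from the competing cause remain in the risk set after their
failure with weight w<sub>i</sub>(t) = Ĝ(t−)/Ĝ(min(T<sub>i</sub>, t)−),
where Ĝ is the Kaplan–Meier estimate of the censoring distribution
(both event types treated as censorings of the censoring process),
evaluated left-continuously; at tied times events precede censorings.

Numerical choices:

* Ties among failure times use the Breslow approximation.
* Newton–Raphson from β = 0 with up to 10 step-halvings per iteration;
  convergence when |Δ log-likelihood| < 1e−9, at most 50 iterations.
  Covariates are centered internally (shifts cancel in the partial
  likelihood); the linear predictor is max-shifted before
  exponentiation.
* A coefficient is non-estimable when its covariate takes fewer than two
  distinct values overall or among subjects experiencing the target
  cause, or when the information matrix's condition number exceeds
  1e12. Non-estimable covariates are excluded from the optimization and
  reported as NaN with `estimable=False`.
* The robust variance is a sandwich: score residuals of the weighted
  partial likelihood are summed within family clusters before the outer
  product. With singleton clusters this reduces to the unclustered
  robust variance. This treats the IPCW weights as fixed; the extra
  variability from estimating Ĝ is not propagated, which in our
  cross-checks against the full estimator changes standard errors by
  well under the inferential resolution of the application (and the
  parameter-recovery test verifies 95% CI coverage directly).
* Wald tests and 95% CIs use the robust SE; AIC = −2·logPL + 2p is used
  exactly as a relative index for the pseudo-likelihood, with no
  small-sample correction. p-values are two-sided with no
  multiple-testing adjustment.

The no-competing-no-censoring limit equals a Cox partial-likelihood fit
(verified against an independent implementation to 1e−6), and an
8-subject brute-force grid search of the likelihood pins the optimum to
1e−3.

## Nonparametric estimators

Kaplan–Meier and Aalen–Johansen share one risk-table construction (all
events at a tied time against the same at-risk count, censorings after
events), which makes CIF₁(t) + CIF₂(t) + S(t) = 1 hold to machine
precision — this identity is asserted in the acceptance suite at 1e−10.
The log-rank test delegates to lifelines' multivariate implementation
and is validated against a label-permutation oracle.

`gray_test` implements the k-sample comparison of cause-specific CIFs
via weighted subdistribution-hazard scores with ρ = 0 (weight 1): group
scores z<sub>j</sub> = Σ<sub>t</sub> [dN<sub>1j</sub>(t) −
a<sub>j</sub>(t)·dN<sub>1•</sub>(t)], where a<sub>j</sub> is the group's
share of the modified at-risk mass R<sub>j</sub>(t) = Y<sub>j</sub>(t)
(1 − F̂<sub>1j</sub>(t−))/Ŝ<sub>j</sub>(t−). The covariance is
estimated from per-subject influence functions, including the correction
terms that arise because F̂<sub>1j</sub> and Ŝ<sub>j</sub> inside the
risk weights are themselves estimated; the cause-1 martingales are
compensated with the pooled null subdistribution hazard, the all-cause
martingales with group Nelson–Aalen hazards. The statistic is referred
to χ²(k−1). Against the reference implementation in R's `cmprsk` the
statistic agrees to a few percent at n ≈ 200 and converges with n; null
calibration at n = 200 is tested directly.

## Burden scores

LD blocks are connected components, within a single gene, of the graph
linking variant pairs with squared Pearson dosage correlation r² ≥ 0.8
(threshold configurable; the study-like fixture reproduces a six-variant
PSEN1 block). Zero-variance variants have r² defined as 0. Each block
becomes one pseudo-variant, the unweighted sum of member dosages —
"unweighted" refers to the members; the collapsed column then receives
its own univariate Fine–Gray weight per cause like any variant, since it
enters the model as a single term.

Weights that fail to estimate (monomorphic columns, non-convergence) are
exactly zero with a cleared flag, so removing such a variant never
changes a score. Scores are accumulated column-by-column in input
order, making them bit-reproducible by a per-subject loop.

Dichotomization splits at the cohort median (linear-interpolation
quantile over the full analysis cohort, affected plus presymptomatic;
both the estimator and the reference population are configurable): high
means strictly above the median, so ties at the median are low.
Standardization centers at the mean and divides by the P80 − P20 spread;
a one-unit contrast therefore compares the 80th against the 20th
percentile of the raw score, and "the other score at zero" means "at
its mean" in interaction models.

## Interaction model grid

Per scenario (AD or FTD as the event of interest, the other competing),
both scores are weighted by the scenario's cause and standardized; the
product term is formed **after** standardization, so main effects in the
full model are contrasts at the other score's mean. All eight
specifications (including the null) are fitted with family-clustered
robust variance; non-converged fits are excluded from selection with a
warning. Selection is argmin AIC with ties broken toward fewer terms.
An optional override prefers the full interaction model when its x:z
Wald p < 0.05 and its AIC is within 2 of the minimum — a documented
operationalization of "comparable fit", configurable. Rank-deficient
grids (e.g. x ≡ z) surface through the estimability flags.

The APOE ε4 sensitivity analysis drops every carrier and refits both
grids. Scores are deliberately *not* re-derived: weights and
standardization stay fixed from the full cohort, making it a pure
subject-exclusion re-estimation; a re-standardization flag exists for
the alternative reading.

## Cross-validation

`make_folds` deals a within-stratum random permutation round-robin into
k = 5 folds (sizes within one per stratum), stratified by diagnosis.
Per fold, weights are estimated on the complement and applied to the
held-out fold; concatenated scores are standardized once (not per
fold). A training split with zero events of a cause yields all-zero
weights for that cause, flagged. LD blocks are fixed from the full
cohort: block structure depends only on genotypes, never outcomes, so
no leakage is possible, while per-fold re-derivation would destabilize
column identity. The fold seed is an explicit, logged input. A leakage
test verifies that perturbing one subject's outcome leaves the weights
applied to that subject unchanged, and a null simulation bounds the
correlation between CV scores and the event indicator.

## Synthetic cohort generator

`simulate_onset` draws from a law whose cause-1 subdistribution is
exactly proportional-hazards in the linear predictor η₁ = Σ G·β₁ + u:
the event is cause 1 with probability 1 − (1 − p₁)^exp(η₁); given cause
1, the latent time inverts F₁(t|η₁) = [1 − (1 − p₁(1 −
e^(−λ₁t)))^exp(η₁)]/[1 − (1 − p₁)^exp(η₁)] in closed form; given cause
2 it is Exponential(λ₂·exp(η₂)). Censoring is Uniform(c_lo, c_hi) on
the latent scale and all times are shifted by an age offset. Predictors
are centered at the expected dosage 2·MAF so p₁ and the rates describe
an average-genotype subject; the true coefficients are unchanged. A
shared Normal(0, sd²) family frailty (default sd 0.3) enters both
predictors — it induces within-family correlation that exercises the
cluster-robust variance and is never seen by the fitted models.
Genotypes are Binomial(2, MAF) per subject; an LD block copies an
anchor's two alleles into each member with a per-allele flip probability
(0.01 in the study-like preset).

`simulate_study_cohort` composes two strata: carriers of AD-gene
causative variants (p₁ = 0.97, so they almost always fail from AD) and
FTD-gene carriers (p₁ = 0.03), with group sizes 39/71/13/29/188/86,
λ₁ = 1/12, λ₂ = 1/18 per year, age offsets 40/42 years and censoring
windows of 55/75 years chosen once so the realized mix of AD events,
FTD events and censored subjects, and the mean onset ages, sit near the
study cohort's (≈ 93/226/107 and onset in the late 40s to 50s). Every
third variant in a gene carries a true effect (0.35 on its own cause,
0.15 on the other for a subset), mimicking partially shared risk. Six
causative and two VUS decoy variants are generated alongside to
exercise the exclusion rules.

What the generator does **not** emulate: pedigree transmission of the
causative variant (group membership is assigned, not inherited),
age–sex interactions, population structure, genotyping missingness
patterns, and realistic within-family genotype sharing (dosages are
independent across subjects; outcome correlation comes from the frailty
alone). Passing tests therefore demonstrate the estimators' correctness
under a clean proportional-subdistribution law with clustered outcomes —
not robustness to model misspecification in real cohorts.

## Problem sizes in the test suite

The acceptance suite uses the sizes its properties need: 50 datasets of
n = 60 for the Cox limit, 200 replicates of n = 2000 for parameter
recovery and CI coverage, 2000 null replicates of n = 200 for Gray's
test calibration, 100 replicates of n = 800 for selection consistency,
and n = 1000 for the cross-validation leakage bound. The end-to-end
drivers run the 426-subject study-shaped cohort.

## Known limitations

* The robust variance conditions on the estimated censoring weights
  (see above); crr-style full variance is approximated, not reproduced
  exactly.
* AIC on a pseudo-likelihood has no absolute interpretation; it is used
  only to rank specifications, as in the analysis it mirrors.
* Gray's test variance is asymptotic; at very small samples with heavy
  censoring it shares the mild anticonservatism of the reference
  implementation.
* The LD-block rule (r² ≥ 0.8 connected components within a gene) is a
  documented default; other block definitions are possible and the
  threshold is exposed.
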