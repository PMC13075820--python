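# Methods

## The model

Family-level survival after parasitoid exposure is analysed as a
Gaussian linear mixed model on the proportion of nymphs dead at day 10:

    y = mu + u_dam + u_sire + u_block + u_plant + e

with each random term i.i.d. normal and an intercept-only fixed part,
fitted separately per treatment arm (the exposure contrast itself is
tested by a binomial mixed model, below). Variances are estimated by
restricted maximum likelihood.

The haplodiploid conversion assumes an additive–dominance model without
epistasis, dosage compensation in haploid males, and approximate
Hardy–Weinberg structure. Under those assumptions the sib covariances
give `Var_sire = V_A/2` and `Var_dam = V_A/4 + V_D/2 + V_Ec`, so

    V_A = 2 Var_sire
    V_D = 2 (Var_dam - V_A/4 - V_Ec),  truncated at 0 (flagged)
    V_Ec = Var_block + Var_plant
    V_P = V_A + V_D + V_e,   h2 = V_A / V_P.

Two open choices were resolved as follows. First, V_P follows the
printed decomposition literally and excludes block/plant variance; an
optional broad-V_P mode adds V_Ec to the denominator for sensitivity
analysis (with the published share vector, narrow h² = 0.268 and broad
h² = 0.233). Second, negative implied dominance truncates to zero
rather than erroring, because sampling noise routinely drives the
method-of-moments dominance estimate negative; the result carries a
`dominance_truncated` flag.

## EM-REML implementation

`fit_reml` maximises the restricted likelihood by EM: each variance is
updated to its conditional expectation given the data and current
parameters, which keeps every update non-negative and the restricted
log-likelihood non-decreasing. Convergence is declared when the
relative parameter change falls below 1e-8 (cap 10,000 iterations).
Two algebraically identical routes are implemented — a direct n×n
covariance route and Henderson's mixed-model equations, whose cost
scales with the number of random-effect levels — and the test-suite
asserts they agree to machine precision.

Plain EM approaches a zero-variance boundary only harmonically (the
iterate behaves like 1/t), so the driver layers a SQUAREM-style
extrapolation on top, with two safeguards that preserve monotonicity:
an extrapolated candidate (optionally with near-boundary components
parked exactly at zero) is accepted only if its restricted
log-likelihood does not fall below the plain double-EM step, and any
component parked at zero is re-activated if its score at the boundary
is positive. The likelihood convention includes the +½log|X'X|
error-contrast term (Harville), under which the intercept-only model
with unit residual variance has the closed form
−(n−1)/2·log 2π − ½Σ(y−ȳ)².

Degenerate inputs: a constant response returns an all-zero flagged fit;
factors with a single level are reported as zero-variance (confounded
with the intercept); a rank-deficient fixed design raises.

The treatment effect on mortality is a binomial GLMM
(cbind(dead, alive) ~ treatment + the four random terms) fitted by
penalized quasi-likelihood: iteratively re-weighted calls of the same
REML engine on the logit working response (working predictor capped at
±8; reported effect capped at ±15 under complete separation). PQL has
no marginal likelihood, so the treatment test is a Wald chi-square on
the log-odds effect; the result object records that this approximates,
not replicates, a Laplace-GLMM likelihood ratio. Under the generator's
null it rejects at ≈0.05 (validated over 1000 replicates).

## Life-history models

Egg counts per disk are fitted by NB2 negative-binomial maximum
likelihood (log link; treatment, disk day as a 4-level factor, and
optionally their interaction). Pairs (replicate within plant) are
handled through cluster-robust covariance rather than a fitted random
intercept: likelihood-ratio comparisons between nested mean models need
comparable marginal log-likelihoods, which a PQL random-intercept fit
does not provide. The fit records `mode="cluster_robust"`. Because the
marginal LR ignores within-pair correlation (it over-rejects roughly
four-fold on clustered data), the pipeline's primary treatment test is
the Wald statistic on the cluster-robust standard error with a
t(clusters−2) reference; the LR is reported alongside for nested model
comparisons and calibrates when the pair variance is absent.

Hatch success is modelled as beta-binomial maximum likelihood on the
logit scale — the closed-form stand-in for a binomial GLMM with an
observation-level Gaussian random intercept; both absorb
extra-binomial variation, and the substitution is recorded in the fit
metadata. The overdispersion parameter is the within-observation
correlation rho = 1/(1+theta); at rho = 0 the likelihood is exactly
binomial, and the fitter returns the binomial GLM solution whenever
overdispersion does not improve the likelihood. All-hatched or
none-hatched data yield a flagged boundary fit with the intercept at
±8. Binomial intervals default to Clopper–Pearson (the conservative
exact interval; Wilson is available) at 95%.

## The synthetic-data generator

The generator emulates the two experiments with known truth.

*Survival.* Families are the cross of `n_sires × n_dams_per_sire`
(default 35 × 1, the full-sib design; >1 gives a half-sib design in
which sire variance is separately identifiable). Latent effects on the
link scale follow the sib covariances above, with V_Ec split between
plant, block and dam shares (default 0.6/0.4/0.0, consistent with
reading V_Ec off the plant and block components). Each
family × treatment × replicate row (default 2 replicates, assigned to
plants round-robin; with a single row per family the dam and residual
variances would be confounded) draws a Poisson(25) nymph count and
binomial deaths with survival probability
`inv_link(link(baseline) + effects + N(0, V_e))`. Two links are
provided: logit (liability-style data generation) and identity with
clamping (the scale the Gaussian analysis assumes), so the estimator
can be tested both under its own model and under a harder
data-generating reality. Baselines are per-treatment survival of the
median family (0.97 control / 0.30 exposed); with the default logit
variances (V_A=0.2, V_D=0.25, V_Ec=0.1, V_e=0.25, latent-scale
h² ≈ 0.29) the pooled exposed survival averages ≈0.32 and family-level
survival spans roughly 0–65%, matching the spread described for the
real assay. The generator does not emulate whole-family extinction
events beyond what the variance structure produces, nor wasp behaviour,
melanisation scoring or within-nymph immune dynamics.

*Life history.* Per arm: 15 plants × 2 pairs × 4 daily disks. Egg
counts are negative binomial (per-disk size 2) around the treatment
mean totals 37.27 (control) and 21.47 (exposed), modulated by a fixed
disk-day profile peaking on days 2–3 and a mean-corrected pair-level
log-normal intercept (sd 0.6 on the log scale, sized so the spread of
per-pair totals reproduces the reported group confidence intervals).
Hatches are beta-binomial (rho 0.05) at hatch probabilities 0.283 /
0.16, with hatch days drawn from a categorical distribution over days
4–8 post-laying weighted toward days 7–8. The observation window is
configurable because the source descriptions of the window disagree
(days 4–7 versus 7–8 prominence); days 4–8 reconciles them.

Identical config and seed give byte-identical tables; the three random
stages (design, effects, outcomes) use independent named substreams of
the seed.

## Recovery protocols and problem sizes

Heritability recovery uses a half-sib design of 50 sires × 3 dams × 2
replicates × ~25 nymphs with the identity link at baseline 0.5. Because
deaths are binomial, the observed family proportion carries sampling
variance E[p(1−p)/n] beyond the configured residual; the protocol
computes that term in closed form (Poisson-truncated E[1/n]) and counts
it inside V_e when fixing the true h², so truth is defined on the scale
the estimator sees. Dominance is held at 20% of V_P — a non-boundary
value, because with a boundary truth (V_D = 0) the truncated dominance
estimate has a positive mean and depresses ĥ² by up to ≈0.04; that
boundary behaviour is a real property of the printed conversion and is
documented rather than hidden. Across 500 datasets per truth in
{0.1, 0.3, 0.5} the mean ĥ² lands within ±0.01 of truth (tested at the
±0.05 criterion), and mean sire variance within a few percent of V_A/2.
Simulation batches run the REML fitter at tolerance 1e-6; tightening to
1e-8 moves ĥ² by under 2e-3.

Variance-share recovery simulates components proportional to the
published share vector (dam 45, sire 13, block 9, plant 6, residual 24)
in the same half-sib design with ~500 nymphs per family so binomial
noise does not inflate the residual share; REML recovers each share to
within about one percentage point in expectation (per-replicate spread
is several points, so reported values average 80 replicates).

Null calibrations run the PQL treatment test on 35-family paired
designs with equal baselines (1000 replicates), and the life-history LR
tests on a doubled design (30 plants per arm) where their likelihoods
are correctly specified — the fecundity LR null omits the pair random
intercept, the hatch null retains beta-binomial overdispersion, which
the hatch model itself absorbs.

## Known limitations

- The conversion inherits the printed framework: no epistasis, no
  maternal-effect decomposition, no joint scaling test across
  generations; h² should be read as the potential for a selection
  response, not a precise population parameter.
- PQL understates variance components for strongly non-Gaussian
  binomial data; the package documents its treatment test as an
  approximation to a Laplace GLMM, and makes no claim of replicating
  any particular mixed-model software output.
- The cluster-robust fecundity Wald test is mildly anticonservative at
  few clusters (rejection ≈0.06–0.08 at 60–120 clusters in the
  validation runs).
- With one replicate per family (as in a literal reading of the
  original design) dam and residual variances are confounded; the
  simulator defaults to two replicates, and heritability from
  single-replicate data should not be trusted.
- Passing recovery tests on synthetic data shows the estimators invert
  the generator's structure correctly; real data add features the
  generator omits (unbalanced families, shared F0 ancestry between
  pairings, plant-level confounding), so field estimates carry wider
  uncertainty than the simulation spread suggests.
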