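# Methods note

This note records the statistical model, the defaults and the design
choices behind `targetmle`, and what the test suite does and does not
demonstrate.

## Target parameter and estimator

The target is the average treatment effect ATE = E[Y(1) − Y(0)] of a
binary treatment `A` (1 = dexamethasone, 0 = hydrocortisone) on a
continuous positive outcome `Y` (day-5 neutrophil–lymphocyte ratio),
identified under conditional exchangeability given the measured
covariates `W` (age, gender, ventilation status, co-morbidities, HIV
status and baseline NLR), positivity, and consistency.

The estimator is a targeted maximum likelihood estimator for a bounded
continuous outcome.  The outcome is mapped onto [0,1] by
`Y* = (Y − a)/(b − a)`; by default `(a, b)` are the empirical minimum and
maximum of the analysed dataset, configurable to fixed values when
estimates must be comparable across dataset variants.  Because the
transform is affine, the rescaled estimate is exactly equivariant:
replacing `Y` by `cY + d` multiplies ψ̂ by `c` and leaves the
z-statistic unchanged (this identity is tested to 1e-10).

The fluctuation step uses **two** clever covariates by default —
separate coefficients ε₁ on `H₁ = A/g` and ε₂ on `H₀ = (1−A)/(1−g)` —
matching the standard tutorial construction for the ATE of a bounded
continuous outcome; a single-ε mode (covariate `H₁ − H₀`) is available
as an option.  Since `H₁·H₀ = 0` rowwise, the two-coefficient problem
separates into two concave one-dimensional quasi-binomial likelihoods;
a damped Newton solver drives the mean score components below 1e-13.
This stringency is deliberate: the efficient influence curve is centred
only up to the residual score, and the package promises
`|mean(EIC)| < 1e-10` as a checkable identity, which generic IRLS
stopping rules do not deliver.

Truncation defaults: propensity scores to `[0.025, 0.975]`, bounded-scale
outcome predictions to `[0.001, 0.999]`.  These are conventional
positivity safeguards preventing unbounded clever covariates; both are
parameters.  A positivity report (decile histogram of ĝ plus counts of
truncated predictions) accompanies each fit on request.  The 95%
interval uses the fixed quantile 1.959964 for bit-level reproducibility.

Setting ε = 0 reduces the estimator exactly to the G-computation plug-in
(the update function short-circuits, so the identity is bitwise).

## Nuisance learners

Both nuisance functions accept any learner satisfying a two-method
protocol (`fit(X, y, seed) → object with predict`).  Presets:

- `par` — quasi-binomial GLMs for both nuisances (the classical
  parametric construction; the outcome model is logit-linear on the
  bounded scale);
- `sl-dsl` / `sl-nnls` — the V-fold super learner with discrete or
  convex meta-learner over the default library {constant, main-terms
  GLM, GLM with pairwise interactions, gradient-boosted trees};
- `tree` — gradient boosting for both nuisances, the package's flexible
  tree-ensemble variant (an exact Bayesian additive regression trees
  sampler is out of scope; the learner contract is what matters to the
  targeting step).

The outcome stage also accepts gaussian-family learners, with
predictions truncated into the Q-bounds.  This matters for simulation
studies: the generator's truth is linear on the raw outcome scale, so a
gaussian linear learner is the *correctly specified* outcome model
there, while the logit-linear quasi-binomial model is close but not
exact.  Simulation tests that advertise "correct nuisance models" use
the gaussian outcome learner for that reason.

Super learner choices: V = 10 folds by default (conventional for
cohorts of a few hundred; the study pipeline exposes it).  Gaussian CV
risk is mean squared error; binomial CV risk is the negative Bernoulli
log-likelihood (proper scoring rule per family).  The convex
meta-learner minimises the family's own CV risk over the probability
simplex — simplex-constrained least squares for gaussian, simplex-
constrained negative log-likelihood (convex) for binomial, combining on
the probability scale.  Solving the simplex-constrained problem (rather
than normalising an unconstrained non-negative least-squares solution)
is what guarantees the orderings the package tests: convex ensemble CV
risk ≤ discrete winner ≤ every base learner, to 1e-9.  The active-set
NNLS solution seeds the optimiser; a second solver (trust-constr, an
augmented-Lagrangian-style method) is exposed behind a flag and must
agree in achieved risk to 1e-6.  Discrete ties break to the lowest
library index, logged.  A learner failing on any CV fold is dropped
with a logged warning rather than failing the ensemble.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
patient data:

- covariate marginals loosely follow the motivating cohort (56% female,
  18% invasively ventilated, 65% hypertensive, 57% diabetic, 12%
  hyperlipidaemia, 8% chronic kidney disease, 4% asthma, HIV
  no/yes/unknown = 79/12/9%; age ≈ N(56, 11²) clipped to [18, 95]);
- day-1 neutrophil and lymphocyte counts are lognormal
  (log-means log 10 and log 0.8, log-SDs 0.45 and 0.40), putting the
  baseline NLR median near 12.5 with IQR ≈ [8.3, 18.8];
- treatment is Bernoulli with log-odds linear in centred covariates;
  the default coefficient on baseline NLR (0.04 per unit) produces a
  treated-vs-control baseline-NLR shift of about 4 units — a clearly
  detectable confounded imbalance — and the default intercept 1.30 is
  calibrated so roughly 76% receive dexamethasone under the default
  covariate mix;
- the outcome mean is `4.0 + 0.85·nlr_d1 + 1.5·vent + 0.8·dm +
  0.5·age_c + 0.4·htn + τ·A` with τ = 2.0 by default and noise SD 2.5.

**Noise and exact truth.**  A plain Gaussian error would put positive
probability on negative NLR values, while truncating or clipping draws
asymmetrically would bias the conditional mean and destroy the
closed-form truth that parameter-recovery tests rely on.  The generator
therefore draws the error from a Gaussian truncated *symmetrically* per
row at `±(μᵢ − floor)` (floor 0.05): symmetry keeps `E[Y|A,W] = μᵢ`
exactly, so the true ATE equals τ exactly in the additive model, while
`Y > 0` almost surely.  Rows whose conditional mean would not exceed
the floor are a configuration error rather than silently clipped.  A
multiplicative log-scale outcome option exists for sensitivity work;
its true ATE comes from Monte Carlo over the covariate distribution
(the conditional means are closed-form, so no outcome noise is
simulated).

Day-5 counts are back-solved — lymphocytes drawn lognormal, neutrophils
= NLR × lymphocytes — and the stored ratio is the literal float division
of the stored counts, so the passive identity `nlr = neut/lymph` is
bitwise exact in generated data.

**Missingness.**  Per-column Bernoulli masking, MCAR or MAR conditioning
on a fully observed binary column (configured rate in stratum 1, rate ×
`mar_ratio ≤ 1` in stratum 0, so stated rates are per-stratum upper
bounds).  Masking an NLR column masks that day's counts in the same
rows (one event per row per day) and vice versa, which keeps the
passive structure coherent and caps the outcome's missingness at its
stated rate.  The study default keeps day-5 NLR missingness at 8% with
moderate (3–5%) covariate missingness; real per-column rates and the
real mechanism are unknown, so these are module parameters, not claims.

**What the generator does not emulate:** ICU admission dynamics,
time-varying treatment or switching, outcome-dependent (MNAR)
missingness, measurement error in counts, and within-patient day-1/day-5
count correlation beyond what the shared baseline-NLR covariate induces.
Passing tests therefore demonstrate correctness of the estimator and
its advertised robustness properties under the stated data-generating
assumptions — not performance on any real cohort.

## Chained-equations imputation

Hand-built chained equations (no off-the-shelf imputer offers PMM
donors, per-column model families and passive recomputation together):
type-0 predictive mean matching with `donor_k = 5` donors (the
conventional default), Bernoulli draws from a fitted logistic model for
binary columns, multinomial-logit draws for 3+-level categoricals with
a ridge fallback for separation in thin strata, and passive
recomputation of both NLR columns from their imputed counts after every
sweep.  Defaults `m = 20` imputations and `maxit = 10` sweeps
(convention; the study pipeline uses smaller values where runtime
matters and says so in its config).  Visit order is ascending
missingness count; predictors are all other analysis columns, with a
day's ratio excluded when imputing that day's counts to avoid
circularity.  Rows with an observed ratio but a missing count are
back-solved (neutrophils = ratio × lymphocytes) instead of modelled.
Initial values are random draws from each column's observed values;
imputation i of m uses the independent stream `(seed, i)`, so the set
is reproducible and individual imputations are order-independent.

Rubin pooling: ψ̄ = mean of points, total variance `W̄ + (1 + 1/m)·B`,
interval from Rubin's small-sample degrees of freedom.  With `m = 1`
the pooled result is the input estimate verbatim (short-circuited so
the identity is bitwise, not just numerical).  The pipeline exposes
both Rubin pooling and a single-imputation mode, since a published
analysis may report either.

## Descriptive table and exact tests

Categorical variables: level counts and within-arm column percentages;
Pearson chi-square (Yates-corrected, the R convention) for 2×2 tables
with all expected counts ≥ 5, Fisher's exact test otherwise — so the
3-level HIV variable always takes the exact path.  The r×c Fisher test
enumerates all margin-preserving tables by depth-first search, summing
probabilities ≤ the observed table's (relative slack 1e-7, as in R),
with a fixed-seed Monte-Carlo permutation fallback (10⁵ draws) when
enumeration would exceed a table-count cap.  Continuous variables:
median [IQR] and a Wilcoxon rank-sum p-value via the normal
approximation with tie and continuity corrections.  With identical
arms the continuity correction leaves p slightly below 1, which is the
expected behaviour of that approximation.

The pipeline's `naive-fill` dataset variant reproduces, transparently,
the median/mode pre-filling some analysis packages apply to incomplete
data; it deliberately omits any censoring-weight correction and is
labelled as such in reports.

## Simulation scales in the test suite

Parameter recovery uses 200 replicates at n = 5000; double robustness
200 replicates per arm at n = 5000 (the doubly-misspecified arm shows a
confounding bias near +2.5 NLR units against a 3-MC-SE band of about
0.04); coverage uses 500 simulations at n = 1000 under randomised
treatment.  The acceptance script re-runs the same checks at 100–300
replicates of n = 1000–2000, and the pipeline's joint-coverage check
runs at reduced scale (20 replicates, n = 400) — sizes chosen to keep
the default runs interactive while leaving Monte-Carlo error well below
the tested tolerances.

## Known limitations

- Tree-ensemble nuisance fits can overfit small cohorts, deflating the
  influence-curve standard error (visible as implausibly narrow
  intervals at n ≈ 168); cross-validated ensembles are preferable there.
- Influence-curve intervals do not propagate imputation uncertainty
  beyond Rubin's rules; imputation can understate total variance when
  the imputation and analysis models disagree.
- No IPCW handling of missing outcomes: missingness must be resolved by
  imputation or complete-case filtering before estimation (the
  estimator refuses incomplete input explicitly).
- Effect measures other than the additive ATE (risk ratios, odds
  ratios) are not provided.
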