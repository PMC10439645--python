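# Methods

## The causal system

The study system is a 17-node DAG over variables involved in cognitive
impairment: exogenous demographics/genetics (age, APOE ε4 carriage, sex),
behavioral and clinical mediators (education, BMI, hypertension, alcohol
abuse history, smoking history, cardiovascular events history), CSF
biomarkers (tau, amyloid-β), the binary outcome `cogn` (cognitive
impairment), and its consequences (hippocampal, ventricular and intracranial
volumes, FDG-PET, MMSE).  A node is exogenous iff it has no parents; the
outcome's parents/children and the exogenous set define the four predictor
schemes (`all`, `parents`, `children`, `exogenous`).

d-separation is decided by the moralized-ancestral-graph criterion
(restrict to ancestors of the query nodes, marry co-parents, drop edge
directions, delete the conditioning set, test connectivity), which is
equivalent to path blocking; the test suite checks it exhaustively against a
path-enumeration oracle on all 5-node DAG structures.  The implied-independence
basis lists, for every non-adjacent pair, independence given the union of the
two parent sets — a valid separating set for any non-adjacent pair, since by
acyclicity no parent of either endpoint can be a common descendant of the
pair.  Conditional-independence tests use sample partial correlation via
least-squares residualization with a two-sided Fisher-z p-value; binary
variables enter on their 0/1 coding (polychoric alternatives are out of
scope).

## Structural equations

Each endogenous node has one equation on the z-scale.  Continuous `y`:
`y = β₀ + Σ βⱼ xⱼ + ε`, `ε ~ N(0, σ)`.  Binary `y`: latent score
`β₀ + Σ βⱼ xⱼ + ε` with standard-normal `ε` and event iff the score exceeds
zero (probit; the intercept absorbs the threshold).  A standard-logistic
latent residual is also supported for constructing correctly specified
logistic-regression benchmarks.

Estimation is equation-by-equation: ordinary least squares for continuous
targets (residual sd with ddof = n − p − 1) and probit maximum likelihood
for binary targets.  For a fully recursive system with independent errors
this targets the same structural coefficients as a system-wide fit, and each
equation's estimate is independent of the others (asserted bit-exactly).
Full-information estimators, standard errors and fit indices are non-goals;
externally estimated parameters can be loaded from the JSON parameter file
instead of re-fit.

z-normalization uses the sample standard deviation (ddof = 1, the `scale()`
convention); the recorded means/sds allow exact inversion and convert
natural-scale intervention values (e.g. "mean age 35, sd 10 years") to the
z-scale on which simulation runs.

## Semi-synthetic generation and interventions

Exogenous variables are drawn by bootstrapping rows *with replacement* from a
source table (preserving their joint distribution; per-column resampling and
fully parametric marginals are also available).  Endogenous nodes are then
simulated in topological order from the equations.  External settings are
declared interventions:

* `replace_exogenous` — redraw one exogenous variable from a normal
  distribution (natural-scale specs converted via the normalization info);
* `set_prevalence` — redraw a binary exogenous variable from a Bernoulli;
* `override_mechanism` — swap the intercept and/or individual coefficients of
  one equation before simulation.  The parameter set itself is never mutated.

The six shipped settings: `train` and `internal` (no intervention, fresh
draws each), `age` (mean age 73.9 → 35, sd 10), `age2` (→ 65), `apoe4`
(carriage 46.9% → 5%), and `tau` (tau-equation intercept −0.5 → 0.9, age
coefficient 0.37 → 0.9, apoe4 0.57 → 0.8, hypertension 0.14 → 0.9, alcohol
0.57 → 0.001).

Seeding is counter-based: cohort seeds are
`SeedSequence(master, spawn_key=(repetition, setting_index))`, so any single
cohort is reproducible in isolation, repetitions are order-independent, and
resumed runs are bit-identical to uninterrupted ones.

## The fixture system

The shipped parameter set carries the published point estimates where point
estimates were printed (age→tau 0.37, apoe4→tau 0.57, hypert→tau 0.14,
alc→tau 0.57, tau intercept −0.5, age→abeta −0.14, age→cogn −0.13,
age→hypert 0.11, age→cardio 0.13).  All remaining values are invented
fixture defaults (`provenance="fixture"`), chosen once so that z-scale
variances stay near one, binary prevalences match the baseline table
(hypertension 34%, cardiovascular history 68%, smoking 24%, alcohol 2.5%),
and the internal-setting outcome prevalence is ≈ 0.70.  The outcome
intercept (0.48) was calibrated to that design target by simulation.

The baseline-cohort generator emulates the analysis-ready baseline table
only *marginally*: continuous variables are normal with mean set to the
published median and sd to IQR/1.349 (age 73.9 [69.2, 78.9]; education 16
[14, 18]; BMI 28.31; CSF-tau 257.8; CSF-Aβ 854.2; MMSE 28), binary variables
Bernoulli at the published prevalences (APOE ε4 0.469, male 0.551, outcome
0.699).  Volumetric and FDG-PET marginals are not published in the baseline
table and are invented (flagged `invented=True`).  Optional Gaussian-copula
knobs can induce small exogenous correlations (e.g. age–APOE ε4); they
default to zero.  Real-data features deliberately not emulated: skewness
(CSF-tau is right-skewed in reality — immaterial here because all modelling
runs on z-scores), missingness, site effects, and selection into the study.
Consequently, passing tests demonstrate properties of the method under a
known linear-Gaussian/probit data-generating process, not fidelity to any
real cohort.

## Prediction models

* logistic: unpenalized maximum likelihood (lbfgs);
* lasso: L1 logistic regression, penalty selected by 10-fold seeded
  stratified cross-validation minimizing deviance over 100 log-spaced
  penalty values (fixed wide grid C ∈ [1e-4, 1e4]); refit per repetition;
* random forest: 500 trees, floor(√p) candidate variables per split;
* GBM: 100 trees, depth 3, learning rate 0.1, deviance loss.

Tree-ensemble probabilities are *not* recalibrated — their internal
miscalibration is part of the phenomenon under study.  All fits are
deterministic given the repetition-derived seed.

## Metrics

**ICI**: mean |p̂ − f(p̂)| with `f` a local-linear tricube-weighted smooth
(span 0.75, the cited reference-implementation convention; exposed in
config), clipped to [0,1].  For n > 5,000 the smoother is evaluated on
anchor points every 1% of the prediction range and linearly interpolated;
the calibration curve is smooth at that scale and the induced error is
< 1e-5.  If all predictions coincide, the smoother is degenerate and ICI
falls back to |mean prediction − event rate|.

**Brier decomposition**: forecasts are grouped into decile (quantile) bins
of p̂; ties at a bin edge fall to the lower bin; bins left with ≤ 1 member
are merged into a neighbor (logged) so the within-bin variance needed by the
bias correction exists.  The Murphy components REL/RES/UNC are computed on
the binned forecasts, for which REL − RES + UNC equals the binned Brier
score *exactly*; the raw (unbinned) score is reported alongside.  The
published small-sample corrections subtract the within-bin sampling term
n_k ō_k(1−ō_k)/(n_k−1)/N from REL and RES and add ō(1−ō)/(N−1) to RES and
UNC; corrected reliability can be slightly negative and is reported as
computed.

**AUC**: Mann–Whitney with the ½-tie convention, via mid-ranks.

**Deltas and summaries**: transport deltas are exact internal-minus-external
differences within a repetition (negative calibration delta ⇒ degraded
external calibration; positive AUC delta ⇒ degraded external
discrimination).  Summaries are the median and the empirical 2.5/97.5
percentiles with the linear-interpolation (type-7) quantile convention.

## Experiment engine

Each repetition regenerates all cohorts, refits all models, and evaluates
every metric in every non-training setting.  Failed repetitions (e.g. a
single-class cohort at small n) are skipped and counted; a failure rate
above 1% aborts the run.  Records stream to CSV per repetition so
interrupted runs resume exactly.  Default desk-scale profile: cohorts of
10,000, 200 repetitions (the reference experiment used 10,000 repetitions;
percentile intervals widen accordingly at reduced counts).  The acceptance
script uses 100 repetitions with logistic models, which bounds its
Monte-Carlo error on median deltas to a few thousandths.

## Known limitations

* Single-variable interventions only; real distribution shifts move many
  variables jointly.
* Linear structural equations with homoscedastic residuals; the latent-probit
  link's printed-coefficient interpretation follows the latent-threshold
  convention, and the parameter file records the link explicitly so other
  interpretations can be encoded.
* Per-equation estimation provides no global fit statistics and assumes
  uncorrelated structural errors.
* The fixture's invented coefficients make the system more discriminative
  (internal AUC ≈ 0.88–0.96) than a real memory-clinic cohort; qualitative
  transport patterns, not absolute performance levels, are the object of
  study.
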