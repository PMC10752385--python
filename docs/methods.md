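# Methods

## The perturbation model

`nlpsens` treats an NLP-derived binary predictor as a noisy observation
of an unobservable truth, characterized entirely by the tool's positive
and negative predictive values. Conditional on the observed calls, a
simulated truth vector is obtained by flipping exactly

    k_P = round(N_P × (1 − PPV))   positive calls to negative,
    k_N = round(N_N × (1 − NPV))   negative calls to positive,

each subset drawn uniformly without replacement. This construction has
two useful exactness properties, both enforced by tests: the Hamming
distance between input and output equals k_P + k_N, and — treating the
perturbed vector as truth — the realized PPV and NPV are exactly
(N_P − k_P)/N_P and (N_N − k_N)/N_N.

The flips are **non-differential**: they do not depend on the outcome or
the covariates. This is an assumption of the error model, and the classic
consequence — attenuation of the exposure effect toward the null — is
verified against a brute-force oracle (below). Differential
misclassification, continuous NLP scores, and multi-class outputs are out
of scope.

Degenerate profiles (PPV or NPV = 0) are rejected: the scheme presumes
mostly-correct calls.

### Rounding of fractional flip counts

N_P × (1 − PPV) is rarely an integer. The default rule is *nearest
integer, ties away from zero*: deterministic, symmetric, and off by less
than one subject. A *stochastic* rule (floor, plus a Bernoulli draw on
the fractional part) is available; it preserves the expected flip count
exactly at the cost of replicate-to-replicate variation in k. Inputs are
snapped to 9 decimals before rounding so that binary-float artifacts
(e.g. `100 × 0.05 = 5.000000000000004`) cannot shift a tie.

### Seeding

One master seed drives a `numpy.random.SeedSequence`, which spawns one
independent substream per replicate. Each replicate records its
substream's integer seed, so any single replicate can be reproduced in
isolation and results are independent of execution order (replicates run
sequentially, but a parallel runner could be substituted without changing
any output).

## Model fitting

Three families cover the designs the pipeline emulates:

- **cox** — Cox proportional hazards, Efron tie handling, Wald p-values.
  With `weighting="propensity"`, stabilized
  inverse-probability-of-treatment weights are estimated from a logistic
  propensity model of the exposure on the confounders
  (`P(A=1)/p̂ᵢ` for exposed, `(1−P(A=1))/(1−p̂ᵢ)` for unexposed) and the
  fit uses a robust (sandwich) variance. Raw weights are available by
  flag; stabilized is the default because its variance is bounded.
  The propensity model is **re-estimated inside every replicate** from
  the perturbed exposure: weights are a function of the exposure, so
  holding them fixed would mix the observed and simulated exposures.
  (Fixed weights can be emulated by pre-computing a weight column;
  re-estimation is the pipeline default.)
- **logistic** — GLM with binomial family and logit link.
- **linear_mixed** — random-intercept linear model fitted by REML.

All families report two-sided Wald p-values computed as
`2·Φ(−|coef/se|)` (the default of the standard implementations of these
estimators), a uniform parameter table (coefficient on the log scale for
cox/logistic with `native_estimate = exp(coef)`; identity for the mixed
model), and a convergence flag. Non-convergence is a recorded state, not
an exception — except for the *original* fit, whose failure aborts the
analysis because there is nothing to compare replicates against. Missing
values are an input error: the analysis is complete-case only.

### Assumption battery

Replicates whose fit violates family-specific diagnostics are retained
in the record, flagged, and excluded from summaries only; the exclusion
count is part of every output artifact. The checks (thresholds
configurable):

- all families: convergence;
- cox: global proportional-hazards test — per-covariate scaled-Schoenfeld
  tests (rank time-transform) combined by Fisher's method, failing when
  the combined p ≤ 0.01. Calibration is verified by simulation: on
  well-specified cohorts the check passes ≥ 95% of repeats;
- logistic: separation screen — any |coefficient| > 10 fails;
- linear_mixed: non-singular random-intercept variance, judged by the
  restricted likelihood ratio against σ_b² = 0 (valid because the fixed
  effects are unchanged, so REML likelihoods are comparable), failing
  when the statistic falls below 3.84 (the χ²₁ 95% point; conservative
  for a boundary-mixture null). A plain threshold on the estimated
  variance proved useless here: at realistic sizes the REML estimate of
  a truly-zero variance is positive noise of order σ_e²/√(n·m), so the
  likelihood-ratio formulation is what actually detects boundary fits.

## Summaries

For each variable, percent change is `100 × (simulated − original) /
original` **on the natively reported scale** and with the *signed*
original in the denominator, so a fixed effect of −1.43 moving toward 0
reports a negative change; a log-scale variant is available by flag.
Quantiles use linear interpolation (type 7, the numpy default). Because
both "mean % change" and "median change" are common reporting choices,
the per-variable summary carries mean, median, and IQR. Sign changes are
judged on the coefficient (log) scale, where "direction" for an HR/OR
means crossing 1. Significance transitions at two-sided α = 0.05
(configurable): *eliminated* iff original p < α ≤ replicate p, *acquired*
iff replicate p < α ≤ original p. Exactly one of the two rates is defined
per variable, by its original significance stratum.

Confounder metrics are pooled over all confounder × included-replicate
pairs; transition rates are reported both as the unweighted mean over
confounders in the relevant stratum and as the pooled-pair rate (the two
coincide when every variable is present in every included replicate, but
both are emitted because either pooling convention is defensible).

B defaults to 500 replicates. B counts *requested* replicates;
assumption-check exclusions reduce the included count, which is reported
alongside every summary.

## The synthetic-cohort generator

Real subject-level EHR extracts are not shareable, so the generator
produces cohorts with a known truth for every downstream stage:

- **survival**: exponential event times with hazard
  `baseline × exp(β·A + Σγ·X)`. The constant baseline keeps the oracle
  simple and costs no generality for Cox estimates, which are invariant
  to the baseline shape (a scale-invariance test enforces this).
  Censoring is independent exponential with its rate solved numerically
  (Brent's method on the mean of `c/(c+hᵢ)`) to hit the requested
  censored fraction.
- **binary**: Bernoulli outcome with logit `baseline + β·A + Σγ·X`.
- **longitudinal**: `measure = baseline + bᵢ + β·A + Σγ·X + e_ij` with
  `bᵢ ~ N(0, σ_b²)` and `e_ij ~ N(0, σ_e²)`, a fixed number of visits per
  subject.

Confounders are generic (bernoulli or normal), each with an effect on
the outcome's linear predictor. Exposure is Bernoulli at the requested
prevalence, optionally made dependent on confounders through a logistic
assignment model so that confounding — and hence propensity weighting —
can be exercised.

The **observation layer** maps the true exposure through a classifier
with given sensitivity and specificity, independently per subject. The
defaults (sensitivity 0.89, specificity 0.969, prevalence 0.10) were
chosen once so that the Bayes closed forms give realized PPV ≈ 0.76 and
NPV ≈ 0.99 — the weakest error profile among the NLP tools the pipeline
emulates; stressing the procedure where tools are weakest is the
informative default. Tests verify that realized PPV/NPV converge to the
closed forms and that each generator family recovers its true effect
with nominal 95% CI coverage.

What the generator does **not** emulate: real covariate distributions or
EHR coding, correlated confounders, time-varying exposures, informative
censoring, visit-count heterogeneity, and error rates that vary across
patient subgroups. Passing tests therefore demonstrate the correctness
and calibration of the *procedure*, not the robustness of any particular
real-world study.

## Verification against an independent oracle

For a no-confounder logistic cohort the replicate OR is the sample
cross-product ratio of the exposure × outcome 2×2 table, and the flip
mechanism induces hypergeometric distributions on the cell displacements.
The exact expectation of the replicate OR is therefore computable by
brute-force enumeration over the two flip-count distributions. The test
suite checks (n = 4000, prevalence 0.3, true OR 3, PPV = NPV = 0.85,
B = 2000) that the mean replicate OR matches this enumeration within
3 Monte Carlo standard errors and that the mean |log OR| is attenuated
relative to the original fit.

## Problem sizes

Simulation-based tests and the acceptance script run at desk scale —
cohorts of 300–4000 subjects (up to 50,000 for law-of-large-numbers
checks of the observation layer), 100–500 replicates, 100–200 repeats
for coverage — sizes chosen so the full suite completes in minutes while
keeping Monte Carlo error well below the tested tolerances (3 SE bands
throughout). At these sizes the mixed-model scenario under the weakest
error profile shows substantial estimate swings and frequent loss of
significance; with the much larger cohorts typical of EHR studies the
same error profile perturbs far fewer calls relative to the information
in the data, so desk-scale volatility should be read as a property of
the scenario, not of the method.

## Known limitations

- The error model conditions on the observed call counts; PPV/NPV are
  treated as known constants, not estimated with uncertainty.
- Only non-differential, subject-independent errors are simulated.
- The linear mixed family supports a single random intercept (no random
  slopes, no nested grouping).
- No multiple-testing correction is applied across confounders; the
  pooled confounder summary is descriptive.
- Percent change divides by the signed original estimate and is
  undefined for an original estimate of exactly 0 (an error, by design).
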