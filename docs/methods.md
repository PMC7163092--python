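# Methods

This note documents the statistical model, the estimation machinery, the
synthetic data the package is validated on, and the design decisions taken
where the methodology left room.

## Pair-indicator features

For genes a, b and sample s the feature is the within-sample ordering
indicator `1[expr(a, s) > expr(b, s)]`; ties score 0 (the "otherwise"
branch is taken literally, which only matters for integer-valued or
heavily rounded data).  Pairs are enumerated once per unordered pair in
canonical orientation (first gene lexicographically smaller); the Cox
coefficient sign absorbs directionality, so no information is lost
relative to enumerating both orientations.

Any strictly increasing transform applied per sample preserves every
indicator, hence all downstream scores, groups and test statistics.  This
is the package's central invariant and is enforced by property tests and
an end-to-end bit-identity check under log, power and per-sample affine
distortions.

**Prevalence filter.**  A pair whose indicator takes one value in more
than 90% of samples (strict inequality, checked separately in the training
and testing splits; exceeding the threshold in either split discards the
pair) is near-constant and both uninformative and unstable under
resampling.  The threshold is configurable; 0.90 is the default.

## Prescreening

Each surviving pair defines a two-group comparison (indicator 0 vs 1) of
overall survival, tested with the standard one-degree-of-freedom log-rank
statistic — hypergeometric variance at each distinct event time, which
accommodates tied event times natively.  P-values are adjusted by
Benjamini–Hochberg step-up (via `statsmodels`) and pairs with q < 0.01
are retained.  Pairs whose indicator is constant in the screened cohort
(possible because the prevalence filter is computed on other splits) are
skipped with a logged warning rather than raising.  The per-pair screen is
vectorized over pairs in chunks so cohorts with ~10⁵ pairs remain
tractable.

## L1-penalized Cox regression

The estimator minimizes `f(β) = NLL(β)/n + λ‖β‖₁`, where NLL is the
negative Cox partial log-likelihood with **Breslow** tie handling (chosen
as the simplest convention consistent across all components;
month-resolution data has ties, and the univariate/multivariable fits done
through `lifelines` use Breslow as well).

The solver is a **proximal Newton** method:

* at the current linear predictor, compute the exact gradient and the
  exact Hessian of NLL/n restricted to a working set (active coefficients
  plus coordinates whose score exceeds λ);
* solve the L1-penalized quadratic model by cyclic coordinate descent in
  coefficient space;
* line-search the resulting direction on the true objective (step
  halving), iterate until the largest coefficient change is below 1e-7,
  and accept only after a full KKT verification.

Every returned solution is certified against the KKT conditions of the
convex objective: `|g_j| ≤ λ` for zero coefficients and
`g_j + λ·sign(β_j) = 0` for active ones, with relative tolerance 1e-4
(violations in practice are ~1e-10).  λ ≥ λ_max (the largest absolute
score at β = 0) provably yields the zero solution and is returned as such.
At λ = 0 the solver reduces to unpenalized Newton and agrees with an
independent Cox implementation to ~1e-6.  The numerical core is
numba-compiled because model-size selection runs thousands of
regularization paths.

**Cross-validated penalty.**  The path has 100 log-spaced values from
λ_max down to 0.01·λ_max, warm-started.  K-fold deviance uses the
Verweij–van Houwelingen form, 2·[NLL_full(β̂₋ₖ) − NLL_train(β̂₋ₖ)],
which stays defined when a held-out fold alone has too few events.  Folds
are reshuffled (up to 10 times) until every fold contains at least one
event.  The default rule takes λ at the minimum mean deviance; the
one-standard-error rule is available as a config switch.

**Repeated selection.**  The CV choice is repeated (default 1000
iterations; iteration i seeds its folds with `base_seed + i`) and the
support of the full-data path solution at each iteration's λ* is recorded.
The final model is the most frequent support among iterations of the modal
support *size* (size ties resolve toward the larger model, support ties by
best mean CV deviance, then lexicographically), refit by the L1 solver on
the full training data at the median λ* of the matching iterations.  The
alternative `best_deviance` rule (single best CV iteration) is available.
This modal-support construction is one reasonable reading of
"most stable model"; it is deterministic given the base seed, which the
repeated-run byte-identity test relies on.

## Risk stratification

The risk score is the linear signature score `Σ_k β_k s_k`.  Cohorts are
dichotomized at their **own median** (each validation cohort at its own
median score; the frozen training median is stored in the signature file
for the fixed-cutoff alternative).  Scores exactly at the median go to the
low-risk group, which gives a deterministic 103/104-type split on odd
cohorts with distinct scores.  One deliberate exception: when a coarse
score distribution (e.g. a one-pair signature) places a strict majority of
patients exactly at the median, the `>` rule would empty the high-risk
group, so boundary scores then move to the high-risk group instead; this
keeps both groups populated whenever scores are not constant and is
logged when it triggers.

Group comparisons report the log-rank test, the hazard ratio from a
univariate Cox fit on the group indicator (Wald 95% CI), and Kaplan–Meier
curves with Greenwood-variance confidence bands (`lifelines`).  The
multivariable model adjusts for age (dichotomized at 60 years), sex
(male vs female) and TNM stage (I/II vs III/IV); patients with missing
covariates are dropped and counted, rank-deficient designs raise, and
suspected separation flags the summary rather than failing.  Subgroup
analysis reruns the group comparison per stratum level and reports NA
rows for degenerate strata.

## Evaluation metrics

**Harrell's c-index** uses the original convention: usable pairs are
(i, j) with `t_i < t_j` and `event_i = 1`; tied scores credit 1/2; tied
times are unusable.

**Time-dependent ROC** at horizon t uses the cumulative-case /
dynamic-control definition — cases are observed events by t, controls are
patients still at risk beyond t — with inverse-probability-of-censoring
weights `1/Ĝ(t_i⁻)` from the Kaplan–Meier estimate of the censoring
distribution.  This keeps the ROC curve monotone, reduces exactly to the
static ROC when no censoring occurs before the horizon, and tracks the
latent uncensored AUC within Monte-Carlo error under heavy censoring
(verified against scikit-survival's IPCW estimator).  Default horizons
are 12, 36 and 60 months (1/3/5-year survival).

## Synthetic cohorts

The generator emulates the structure of the public hepatocellular cohorts
the method is used on — hundreds of immune genes, 100–400 patients,
roughly 17–39% deaths with the rest censored, ~10-year maximum follow-up,
platform/batch differences — without downloading anything.

* **Expression**: per-gene log-normal marginals, location U(0.5, 4.0) and
  scale U(0.2, 1.0) on the log scale, so non-planted pair prevalences span
  the filterable and non-filterable ranges.
* **Planted effects**: a chosen number of gene pairs get equalized
  location parameters (their indicator is then a fair coin, so planted
  pairs survive the prevalence filter) and contribute
  `Σ_k β_k s_k` to the log-hazard.
* **Survival**: exponential proportional hazards,
  `h = h₀·exp(Σ β_k s_k)` with h₀ = 0.01/month by default (median
  survival ≈ 69 months at baseline), chosen for its closed-form medians
  (`log 2 / h`) which the generator is tested against.
* **Censoring**: independent exponential whose rate is solved numerically
  (bracketed root-finding on the exact censoring probability) so the
  expected censoring fraction hits the target — default 65%, matching a
  ~35% death rate — plus an administrative cutoff at 120 months.  Targets
  below the administrative floor raise.  The per-cohort realized fraction
  fluctuates binomially around the target (SD ≈ 2.7 points at n = 300).
* **Batch effects / platforms**: optional per-sample multiplicative
  factors and the monotone distortion kinds (log, power, per-sample
  affine, rank-preserving noise) emulate cross-platform scale differences.

What the generator does **not** emulate: gene–gene correlation beyond
what planted pairs induce, realistic immune co-expression modules,
non-proportional hazards, informative censoring, and probe-level noise
structure.  Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the stated model, not performance on
real cohorts.

One consequence worth knowing: pairs sharing a gene with a planted pair
("shadow pairs") have correlated indicators and are genuinely marginally
prognostic, so full-cohort discovery legitimately returns them alongside
planted pairs — the same reason real signatures contain correlated
partners.  Recovery studies that need exact support identification
therefore plant pairs among null pairs built from disjoint genes.

## Study sizes used by the validation studies

The packaged studies (test suite and `scripts/acceptance.py`) run at desk
scale, chosen so the full suite completes in minutes on one CPU:

* selection-protocol recovery: 3 planted pairs (|β| = 1.5) among 250 null
  pairs, n = 400, FDR-0.01 screen on the full cohort, 200 CV-lasso
  iterations, 6–10 replicates;
* null control: 60 genes, n = 200, 10–20 seeds, 25-iteration selection on
  a 50/50 split with held-out c-index;
* KKT certification: 20 random instances, n ∈ [80, 200], p ∈ [3, 25],
  penalties from 0 through 1.5·λ_max plus CV-chosen values;
* end-to-end discovery/determinism: 40 genes, n = 240–260, 30–50
  iterations.

## Known limitations

* Breslow (not Efron) ties throughout; with heavy tying Efron is usually
  preferred.
* The modal-support rule can be unstable when no support dominates; the
  tally and per-iteration log are written out so users can inspect the
  frequency table, as one would with any stability-selection procedure.
* IPCW weights use the unconditional censoring KM; covariate-dependent
  censoring would need a conditional censoring model.
* The c-index is reported without a confidence interval; comparisons
  between signatures are point estimates ordered by c-index.
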