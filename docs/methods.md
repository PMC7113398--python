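# Methods

## The analysis model

The pipeline treats overall survival (OS, months, right-censored) as
the outcome and binary HLA superallele carriage plus clinical
covariates as exposures. Group contrasts are measured under the Cox
proportional-hazards model: for a binary split the reported hazard
ratio is exp(β̂) from a single-indicator Cox fit oriented so HR > 1
means the designated high-risk group dies faster, with the 95% CI
exp(β̂ ± 1.96·se) and, for group comparisons, the log-rank p-value
(Wald p is kept alongside). Kaplan–Meier curves are the product-limit
estimator.

### Cox fitting

`hlasurv.survstats.fit_cox` maximizes the partial likelihood by
Newton–Raphson with step-halving. Ties use the Efron correction by
default (month-resolution survival data is heavily tied; Efron is also
the default of the R `survival` package, easing cross-checks), with
Breslow behind a flag; the two coincide exactly on tie-free data, which
the tests assert. Covariates are mean-centered internally and the
linear predictor is shifted by its maximum before exponentiation, both
purely for numerical stability. Convergence is declared when the
largest score component falls below 1e-9 or the relative log-likelihood
change falls below 1e-10, within 100 iterations. Constant covariates
are rejected up front. A monotone likelihood (perfect separation,
detected as a coefficient drifting beyond |β| = 15 ≈ HR 3×10⁶) raises
an error naming the covariate by default; evaluation paths that can
legitimately produce quasi-separated splits (a very sharp predictor
under the median-split rule, a tiny extreme risk-score group) request
the flagged fit instead and surface a `separated` flag rather than a
number presented as a finite estimate.

The score test at β = 0 is exposed separately; for a single binary
covariate on tie-free data it equals the log-rank chi-square exactly
(with ties the log-rank hypergeometric variance carries an
(n−d)/(n−1) factor the Breslow score variance lacks, so the identity
is only asserted untied).

## The superallele screen

Four-digit alleles are collapsed to gene + field1 ("superalleles") and
every superallele carried by ≥ 10 patients is screened: carriers vs
non-carriers are compared on mean observed follow-up months with a
two-sample t-test (Welch by default — carrier groups of 10–20 against
~390 make the pooled-variance assumption indefensible; the pooled form
is a flag). Positive significant difference ⇒ survival-favorable (SF),
negative ⇒ survival-unfavorable (SU), otherwise NS, at α = 0.05.

Two deliberate statistical caveats, faithfully reproduced and worth
stating plainly:

- **Censored times enter the means as plain numbers.** The screen's
  group means are raw observed follow-up, with no censoring
  adjustment. This makes the screen conservative and asymmetric —
  censoring truncates exactly the long survival times a favorable
  superallele creates, so SF effects are systematically harder to
  detect than SU effects of equal size (the simulation studies in the
  test suite show this directly). The censoring-aware analysis of the
  same contrast (Cox HR on the carrier indicator) is available through
  `survstats.group_hazard_ratio` and is what the downstream stages use.
- **No multiplicity correction affects the SF/SU call.** A
  Benjamini–Hochberg column is emitted for the reader but never
  changes the class; with ~25 candidates at α = 0.05 roughly one
  chance call per cohort is expected, and the null-calibration test
  confirms the non-NS rate sits at α on effect-free cohorts.

## Risk score and stratification

RS = (# SU superalleles carried) − (# SF superalleles carried), an
unweighted ±1 sum. High-risk at threshold t means RS ≥ t (inclusive;
the strict variant is a flag). The sweep reports group sizes, HR, CI
and log-rank p per threshold; a split leaving a group empty is flagged
`degenerate`, a split whose Cox likelihood is monotone is flagged
`separated`, and neither aborts the sweep. High-group size is
non-increasing in t by construction.

## Prediction models and evaluation

Regressors (lasso, ridge, random forest, decision tree; scikit-learn)
predict OS months from clinical covariates and carriage indicators.
Age and Breslow depth enter as raw numerics (binary >60 / >3 mm
encodings, used by the univariate/multivariate Cox tables, are a flag);
gender, stage (III+IV vs 0–II) and tumor status are indicators.
Missing clinical values cause listwise deletion within the analysis at
hand, never globally, with dropped counts logged.

Evaluation is stratification power, not squared error: 5-fold CV
out-of-fold predictions are pooled, split at their median (high-risk =
predicted OS strictly below the median; ties at the median go
low-risk), and the HR between the groups is computed on the true
outcomes. Pooling before a single median split is the default (it
corresponds to one KM stratification of the whole cohort); per-fold
HRs are available via a flag, since averaging fold-level performance is
the other defensible reading of 5-fold evaluation. Lasso/ridge choose
their penalty by inner 3-fold CV on the training folds unless an
explicit `alpha` is supplied; tree models use library defaults with the
run seed. All hyperparameters, the seed and a fold-assignment hash go
into the run manifest.

The wrapper is greedy forward selection over a candidate superallele
pool (default: the screened SF+SU set): each step adds the candidate
that maximizes the evaluated HR, provided it strictly beats the
incumbent, else stops — so the trajectory is strictly increasing and
terminates after at most |pool| steps. The fold assignment is frozen
across the whole search so every candidate comparison is paired;
re-randomizing per step is a flag.

External validation refits the model on the full training cohort and
splits the external cohort at the median of its own predictions. A
superallele named in the feature set but absent from the external
cohort's presence matrix is an error (listing the missing columns), as
silently zero-filling can hide an allele-table mismatch; an explicit
`fill_missing_superalleles` flag enables zero-filling for genuinely
allele-poor cohorts.

## The synthetic cohort generator

`simulate` draws, per patient: independent superallele carriage at
configured frequencies; age ~ Normal(58, 14) clipped to [18, 90];
female with p = 0.38; stage from (0, I, II, III, IV) with probabilities
(0.02, 0.20, 0.35, 0.35, 0.08); "with tumor" with p = 0.35; Breslow
depth log-normal (median 2 mm, σ = 0.9). Event times follow the
Weibull proportional-hazards model T = λ(−ln U / e^η)^{1/k} with
η = Σ planted log-HRs × carriage + clinical effects; censoring is an
independent exponential capped at an administrative horizon
(os = min(T, C), event = 1{T ≤ C}) — the non-informative regime under
which KM and Cox are valid. Everything is a pure function of
(config, seed): regenerated cohorts and their TSV exports are
byte-identical. Four-digit allele names (random protein field per
carried group, occasionally two variants) are emitted so simulated
data exercises the nomenclature and cohort-assembly path end to end; a
patient carrying no configured superallele is assigned the most common
one, since real patients always type at several loci.

The default "melanoma-like" configuration emulates a 401-patient melanoma
cohort: 24 superalleles with carriage frequencies equal to the
published carriage counts over 401, plus four common null background
groups. Planted conditional log-HRs are a fixed mix of 7 protective
(−2.2 to −0.8), 12 harmful (+0.7 to +1.6) and 5 null effects; the
magnitudes were chosen so that the *marginal* per-superallele hazard
ratios — attenuated because every other planted effect acts as
unmodelled frailty (HRs are non-collapsible) — land near the published
univariate estimates (≈0.15 for the strongest protective group,
≈2.8–3.4 for the strongest harmful ones). Clinical conditional log-HRs
are 0.2 per decade of age, 0 for gender, 0.8 for stage III+IV, 2.1 for
"with tumor", 1.0 for Breslow > 3 mm, in the ordering (tumor status ≫
Breslow > stage > age ≫ gender) of the published univariate analysis.
The exponential baseline (λ = 550 months for a young, tumor-free,
early-stage non-carrier; covariates raise typical hazards several-fold)
and censoring (rate 0.0115/month, 200-month horizon) are balanced so
that roughly two thirds of patients are censored while mean observed
follow-up stays near 55 months, as in melanoma registry cohorts.

What the generator does **not** emulate: linkage between loci
(carriage is independent across superalleles, no haplotype/LD
structure), population allele-frequency realism beyond the configured
counts, informative censoring, and missing clinical values. Passing
tests therefore demonstrate correctness of the statistical machinery
and recoverability of planted effects under the stated model — not
robustness to LD, informative dropout or measurement error in real
registry data.

## Problem sizes used by the test suite

The distributional checks run at sizes chosen to make Monte-Carlo error
small relative to the asserted bands: Cox CI coverage at n = 1000 over
200 replicates (band 95% ± 3%); log-rank null calibration at n = 80
over 1000 replicates; screen null calibration over 40 effect-free
401-size cohorts (~1000 superallele tests, band 0.05 ± 0.02) and power
at a planted log-HR of ±ln 3, carriage 0.15, n = 400 over 100
replicates (≥ 90% correct, evaluated censor-free since the raw-mean
screen's power is censoring-limited); wrapper recovery of a single
planted effect over 20 seeds (≥ 90% first-pick rate).

## Known limitations

- The screen's raw-mean contrast is not a censoring-aware estimator;
  its group means underestimate true mean survival and its power is
  asymmetric under censoring (see above).
- The Cox implementation covers time-fixed covariates only: no
  stratification, time-varying effects, competing risks or
  proportionality diagnostics.
- Wrapper selection maximizes an in-sample-CV HR greedily; the
  selected set is not guaranteed optimal and the final HR is biased
  upward as a selection maximum — external validation exists for
  exactly this reason.
- Published cohort-level results that depend on the controlled-access
  per-patient table (the full screening table, threshold-sweep group
  sizes, model HRs) are reproduction surfaces only when that table is
  supplied as input; fold randomness and unstated hyperparameters make
  model HRs stochastic targets in any case.
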