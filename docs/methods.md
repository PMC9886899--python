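# Methods

This note documents the models, defaults, numerical choices, and known
limitations of `glbn`. It is the design record a maintainer should read
before changing defaults.

## Cohort model and outcome definitions

A participant's record is a daily attendance/dose series over a fixed
observation window plus one urine-morphine result per calendar month.
Calendar months are modelled as fixed 30-day blocks from enrollment: the
clinics' true visit calendars are unknown, and fixed blocks make every
derivation deterministic. A 6-month analysis window therefore spans 7
observed months (210 days) and a 12-month window 13 months (390 days), the
extra month being the excluded adjustment month.

* **Relapse** — true iff months 2..D+1 contain two consecutive positive
  urine tests. The pair must lie wholly inside the retained window; a
  positive month 1 contributes nothing. The rule is monotone: turning any
  month positive can only switch the outcome from no to yes.
* **Continuous treatment days** — days from the day after the end of the
  last absence run strictly longer than 14 days to the end of the window;
  the full window when no such run exists. A run of exactly 14 days is
  retention, per the strict inequality in the dropout definition.
* **Initial daily dose** — the mean dose over *attended* days among the
  first 7 calendar days (absent days contribute no terms, because dose is
  undefined when the participant is not dosed); missing when no day of the
  first week was attended, in which case the value flows into imputation.
  The sensitivity variant replaces it with the attended-day mean over the
  whole window (`dose_covariate: average`).
* **Discretization** — left-closed/right-open intervals with the printed
  bin labels (dose `<30 / 30-60 / >60` mg; continuous days
  `<30 / 30- / 60- / 90-`). The mapping is idempotent on already-binned
  columns and deterministic.

## Synthetic cohort generator

The generator emulates the two restricted data streams so every downstream
stage is testable. Defaults are the study conditions: n = 903 at 6 months
targeting a 32% relapse proportion, n = 710 at 12 months targeting 39%.

* **Baseline covariates** (10 categorical variables: age, age at initial
  drug use, HIV status, sexual behaviour, job, time to clinic,
  transportation, family relationship, drug-friend contact, living status)
  are drawn by ancestral sampling from a small ground-truth DAG with
  explicit CPTs. Marginals and dependencies were chosen once as plausible
  for a registry cohort (e.g. ~7% HIV prevalence overall, higher under
  high-risk sexual behaviour); they are configuration, not estimates.
* **Relapse propensity** follows a sparse group-structured logistic model:
  four of the ten covariates (HIV status, age at initial use, family
  relationship, drug-friend contact) carry log-odds effects of 0.2–0.9; the
  intercept is calibrated by root-finding so the cohort's mean propensity
  equals the target rate exactly, which puts the realised relapse fraction
  within binomial noise of the target by construction.
* **Urine series** are two-state Markov chains so the two-consecutive-
  positives rule is exercised non-trivially. The adjustment month is
  positive with probability 0.45. Participants drawn as relapsers use
  P(+|−)=0.25, P(+|+)=0.65 and are guaranteed a qualifying run inside the
  assessed window (one is inserted at a random position if the chain
  produced none); non-relapsers use P(+|−)=0.15, P(+|+)=0 and therefore
  never produce a qualifying run. Derived relapse status consequently
  equals the latent Bernoulli draw.
* **Attendance** has a per-day hazard (default 0.004) of starting an
  absence gap, multiplied up for estranged family relationships and weekly
  drug-friend contact, with a mixture of short gaps and >14-day dropout
  gaps — so compliance (continuous treatment days) is associated with
  relapse through shared causes rather than by fiat.
* **Missingness** is MCAR at a configurable rate; the data give no basis
  for an informative mechanism. The outcome is never masked.

What the generator does *not* emulate: the real covariate marginals from
the supplementary tables, informative missingness, seasonal or calendar
effects, re-enrollment, and overlap between the 6- and 12-month cohorts
(simulated cohorts are independent). Passing tests therefore demonstrate
that the pipeline recovers structure it is designed for, not that the
published effect estimates are correct.

## Group lasso

Objective: `Σ_i loss_i + n λ Σ_j w_j ||β_j||₂` with an unpenalised
intercept, one block per dummy-coded variable (first level is the
reference), columns centred and scaled to unit variance before
penalisation, and `w_j = √p_j`. Unweighted penalties (`weights: none`) are
available but over-select large groups. Coefficients are reported on the
original dummy scale.

The printed estimator in the source analysis uses squared loss even though
the outcome is binary; both losses are implemented and the logistic loss is
the pipeline default, which matches the stated pairing of group lasso with
logistic regression for binary outcomes. The discrepancy is recorded, not
resolved.

**Solver.** Block coordinate descent. For squared loss each block update is
the exact block minimiser, computed as a group soft-threshold in the
eigenbasis of the block Gram matrix `X_j'X_j` (the norm of the update solves
a monotone scalar equation, found by bisection to 1e-14 relative). For
logistic loss each sweep majorises the log-likelihood by the quadratic with
curvature bound 1/4 at the sweep's start and applies the same exact block
update to the surrogate; the objective is non-increasing sweep by sweep and
blocks hit exact zeros. Convergence: maximum coefficient change below
`tol = 1e-7`; cap 5·10⁴ sweeps (raised from an earlier 10⁴ after profiling
near-collinear dummy blocks, whose linear convergence is slow but cheap). A
non-convergent single fit raises an error carrying the last iterate. Inner
loops are numba-compiled; a pure-numpy majorise–minimise implementation is
the fallback and reference. KKT residuals at convergence are checked in the
tests (<1e-6).

**Path and CV.** 100 log-spaced λ from `λ_max` (the smallest all-zero
penalty, computed from the KKT bound at the intercept-only model) down to
`1e-4·λ_max`, warm-started. Following standard path-solver practice the
path truncates once >99.9% of the null deviance is explained, which handles
quasi-separation at tiny penalties. Cross-validation is stratified by
outcome (at ~32% prevalence unstratified folds risk outcome-empty folds),
uses the deviance for logistic loss, and selects the λ with minimum mean CV
error by default; the one-standard-error rule (`rule="1se"`) selects the
sparsest model within one SE of that minimum.

**Selection rules and support recovery.** Minimum-CV selection optimises
prediction and is known to over-select: on cohorts with three planted
signal groups among twelve, it keeps all signal groups in every replicate
but admits 2–9 noise groups in most. The 1-SE rule is the standard
prescription when the goal is support recovery; it too retains every signal
group and keeps false inclusions to ≤1 in roughly 80% of replicates under
the default recovery conditions (n=1000, 10-level variables, ±0.8 log-odds
effects). The pipeline default remains minimum-CV, matching the stated
selection rule of the source analysis; the recovery property tests use the
1-SE rule and report the measured rate.

## Bayesian network

* **Score**: decomposable BIC, `Σ_i [loglik_i − ½ log(n) · (r_i−1)q_i]`,
  cached per (node, parent set). BIC is the conventional default for
  score-based discrete structure learning; the source analysis names only
  the search method, so the score is a design decision.
* **Search**: Tabu over add/delete/reverse single-edge moves. The best
  legal non-tabu move is applied even when it decreases the score; the
  inverse move signature is tabu for 10 iterations, with the usual
  aspiration exception for moves beating the best score seen. Acyclicity is
  enforced per move; whitelist edges are present in every visited graph and
  blacklisted edges never appear (expert adjustment is operationalised as
  these constraints, not interactive editing). Stops at 1000 iterations or
  after 25 non-improving moves; move enumeration order is seeded, which
  fixes tie-breaks. The pipeline caps parent sets at 4 to keep CPTs
  estimable at registry sample sizes.
* **Parameters**: maximum-likelihood conditional frequencies; unobserved
  parent configurations get the uniform row and are recorded. No smoothing
  by default (a pseudo-count is available).
* **Inference**: exact variable elimination in min-degree order; factors
  are dense arrays. Evidence with zero probability raises a dedicated
  error (an exact-zero normaliser; at these table sizes underflow is not a
  realistic confounder, and the message says so). Posteriors agree with
  brute-force joint enumeration to 1e-10 on all fixture networks.
* **Risk queries**: Table-style conditional relapse distributions per
  covariate configuration, and an exhaustive max-risk search over the
  Cartesian product of query-node levels (the pipeline uses the outcome's
  Markov blanket, capped at 4096 configurations). Ties at the maximum are
  broken lexicographically and all tied assignments are reported.
* **As a classifier** (for ROC comparison): P(relapse = yes | all other
  observed nodes) by exact inference, cached per distinct evidence pattern.
* **I/O**: BIF text round-trips nodes, edges and probabilities to 1e-6
  (import renormalises row sums within text precision and rejects anything
  worse); DAGs export to edge-list CSV/DOT via networkx.

## Classical statistics

* Pearson chi-square without continuity correction — the uncorrected
  statistic on the published duration table is 8.5745 (printed as 8.58; the
  Yates-corrected value would be ≈8.27, so the published number is the
  uncorrected one). Fisher's exact test is two-sided by summing
  hypergeometric probabilities no larger than the observed table's, with
  the comparison done on exact integer weights so mathematical ties are
  unambiguous; it is restricted to 2×2 tables, and larger sparse tables get
  a collapse recommendation instead. The test chooser applies the stated
  rule: Fisher iff any expected count <1 or more than 20% of cells have
  expected counts <5 (strictly).
* AUC via the Mann–Whitney identity with midranks (ties count one half);
  95% CI by DeLong's method (deterministic), with a seeded bootstrap
  alternative for the paired AUC difference since the source analysis does
  not name its interval method. Model comparison is in-sample by default.
* Multiple imputation: chained equations over categorical columns. Each
  incomplete column is redrawn from the empirical distribution of the
  column conditional on the current completed values of all other columns
  (exact configuration match; marginal fallback for configurations never
  observed complete), sweeping up to 5 times or until no imputed cell
  changes. With ~10 covariates most configurations are unique, so the
  conditional draw often reduces to the matched-donor or marginal draw —
  adequate under MCAR, and the tests check only marginal preservation.
  Chains are independently seeded. Selection is run per completed dataset
  and the modal selected set is carried forward; probabilities are not
  pooled across imputations (no pooling procedure is described for them).

## Pipeline

Stages: derive outcomes → discretize → impute (m datasets) → group-lasso
selection per dataset (modal set wins) → Tabu + MLE network over the
selected variables plus the outcome (the outcome is always included, so the
query target exists even if the screen empties) → risk queries → ROC
comparison of the network against the group-lasso logistic model → JSON/CSV/
BIF artifacts. Every stage failure aborts with the stage name; upstream
artifacts persist. All randomness traces to named seeds recorded in the
report, and a rerun with the same configuration is byte-identical.

## Problem sizes used in the checks

The automated checks run at: recovery simulations n=1000 with 50
replicates of 10-fold CV; structure recovery n=5000 with 20 replicates;
exact-test enumeration over all 2×2 tables with N≤40 (~135k tables);
inference oracles on networks of up to 10 nodes; and full pipeline runs at
n=903 with 2 imputations and a 40-point λ grid. These sizes exercise every
code path at the study's scale while keeping the whole battery to a few
minutes.

## Known limitations

* Fixed 30-day months are an approximation of clinic calendars.
* CV fold fits reuse the full-data column standardisation; at these sizes
  the leak is negligible, but fold-local re-encoding would be cleaner.
* The BN classifier conditions on all observed nodes; it does not handle
  partially missing evidence at prediction time (impute first).
* Exact inference is dense variable elimination — right for a dozen
  categorical nodes, wrong for hundreds.
* No inference (p-values, CIs) on selected group-lasso coefficients, no
  overlapping/sparse-group variants, no Bayesian CPT posteriors, no
  approximate inference, no continuous or hybrid nodes.
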