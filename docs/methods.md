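# Methods

## Model

A juncture model is a structural causal model over a three-level hierarchy
(organizations → practitioners → patients) in which the implementation
process is a chain of binary decisions. Every node has exactly one
structural assignment:

* **latent-utility threshold** (binary decisions D1, D2, T1, and the
  exogenous binary V2): `d = 1[β₀ + β'pa + ε > 0]`, `ε ~ N(0,1)`. The unit
  error scale is an identification normalization — it makes the index
  coefficients the probit coefficients, so probit ML is the correctly
  specified estimator.
* **linear** (all continuous nodes): `y = β₀ + β'pa + ε`, `ε ~ N(0, σ)`.
  Exogenous continuous nodes are the degenerate case with no parents
  (standard normal by default).
* **deterministic sum** (the aggregate cost W = W1 + W2): computed exactly,
  no error.

Bidirected edges denote unobserved correlated errors and are given
latent-common-parent semantics: before any path analysis the graph is
expanded with a fresh hidden node per pair. In sampling, the pair's error
draws are jointly normal at the configured correlation, with the
finer-level member inheriting the coarser unit's shock (perceived
leadership X2 inherits its organization's management-style context Z2,
correlation 0.5), so practitioner values are correlated within
organizations exactly through that shared component.

**Selection.** The decision to implement at all (D1) gates the rest of the
system: the strategy choice, practitioner perceptions, assignment and
follow-up outcomes exist only where D1 = 1. The simulator computes all
branches internally but masks gated variables (NaN) in the public tables
for non-implementing organizations — missing by selection rather than
dropped rows, so negative-control analyses over the full tables remain
possible. Every identification query conditions on D1, because
post-selection estimands are only defined on the implementing branch.

**Scope.** The model covers the exploration, adoption/preparation and
active-implementation phases. Feedback loops (sustainment / continuous
quality improvement), patient compliance junctures, interference between
patients, non-normal error families and time-varying covariates are out of
scope by construction.

## Canonical system and defaults

The canonical CBT system has 20 nodes. The edge list is chosen to satisfy,
simultaneously: the strategy decision D2 has the organizational network
variable Z1 and both strategy costs among its parents; Z1 and X2 confound
the strategy's effect on perceptions (X2 through the Z2↔X2 correlated
error into D2's parent Z2); tenure X3 and the patient variables V1, V2, Y1
enter the assignment decision T1 directly but lie on no back-door path of
the perception effects, making them pure precision covariates there;
socio-economic status V3 drives both baseline and follow-up scores, making
it a precision covariate for the treatment effect; and the two perception
variables X4, X5 share all their parents rather than pointing at each
other, so their mutual dependence is symmetric. `validate_claims` certifies
the encoded graph against each of these identification statements at
construction of every Monte Carlo run.

Default coefficients: intercepts 0; decision indices use coefficients of
magnitude 0.3–0.5 (costs enter negatively); the strategy effect on each
perception is 0.5; the perception effects on the assignment index are 0.4
(feasibility) and 0.3 (appropriateness); the treatment effect on the
follow-up score is 1.0; every confounder enters with 0.3; the baseline
score carries 0.5 into follow-up; the Z2↔X2 correlation is 0.5. All
continuous exogenous nodes are standard normal; gender is Bernoulli(0.5).
With zero intercepts every decision probability averages near 0.5, so both
branches of every juncture stay populated.

Error SDs of the endogenous continuous equations are a package default:
0.5 for the perception equations (X4, X5), 1.0 for the score equations
(Y1, Y2). The perception noise was fixed by a design-time variance
analysis: the strategy estimands are identified from organization-level
variation only (~20 implementing organizations, ~100 practitioners per
draw), and a perception noise of 0.5 keeps the per-repetition relative-bias
spread near 0.25, so the mean over 1000 repetitions resolves bias at the
sub-percent scale the study is meant to demonstrate. This also gives the
perception equations a realistic explained-variance share (~55%).

Hierarchy: 40 organizations × 5 practitioners × 30 patients = 6 000
patients, exposed in configuration. 6 000 matches administrative-database
scale; 40 organizations keeps the organization-level estimands honest about
their limited effective sample size.

## Identification machinery

d-separation uses the standard active-trail reachability algorithm on the
latent-expanded graph. Back-door validity of Z for (treatment, outcome):
no member of Z ∪ {selection} descends from the treatment, and Z ∪
{selection} d-separates treatment from outcome after deleting the
treatment's outgoing arrows. Minimal-set enumeration is an exhaustive
subset search over observed, pre-treatment candidates restricted to
ancestors of {treatment, outcome, selection} (minimal separators cannot
lie elsewhere), ordered by size then lexicographically, pruning supersets
of sets already found — exact and fast at this graph size (≲1 s for the
canonical DAG). All orderings are deterministic so downstream choices
(e.g. the short specification) are stable.

On the canonical DAG the feasibility effect X4→T1 has two minimal
adjustment sets, {Z1, X2, X5} and {D2, X1, X2, Z1}; the package reports
both and uses the first (the set named in the system's identification
discussion) as the short specification. The named set is minimal but not
unique — neither property is assumed, both are computed.

## Sample truths

True effects are defined per sample, not per population. After a draw, the
dataset retains every error draw; an intervention (say T1 := 1) is
evaluated by recomputing all descendant equations with those errors fixed
(abduction–action–prediction). Average treatment effects are mean
potential-outcome contrasts over the eligible (implementing) population;
because the outcome equations are linear, these equal the structural
coefficients exactly in every sample. Effects on decisions are average
marginal effects on the probability scale: mean over eligible units of
`β·φ(index)` at the observed covariates, which a finite-difference replay
reproduces to 1e-6.

## Estimation

Short specifications are certified against the back-door criterion before
any fit (a hard assertion); full specifications add every parent of the
outcome. OLS for continuous outcomes reports the treatment coefficient;
probit ML (Newton, gradient tolerance 1e-8, max 200 iterations) for binary
outcomes reports the treatment's average marginal effect — density-weighted
coefficient for continuous treatments, discrete 0→1 contrast for binary
ones — with delta-method standard errors. The AME rather than the index
coefficient is reported because the truths are defined on the probability
scale. Organization-level treatments get cluster-robust sandwich standard
errors with the G/(G−1) small-sample correction (≈20 effective clusters);
other fits use heteroskedasticity-robust (linear) or information-matrix
(probit) covariance. Exact collinearity, perfect separation, single-class
outcomes and empty eligible samples raise typed errors rather than
returning numbers.

Note the short probit specifications are consistent for the AME even
though they omit independent covariates that belong to the true index:
marginalizing a probit over independent regressors changes the index scale
but not the average derivative of the response probability. The Bernoulli
gender variable makes that marginal not exactly probit; the residual
approximation error is far below the Monte Carlo resolution.

## Monte Carlo design

Each repetition r derives an independent substream seed from the master
seed via `SeedSequence(master, spawn_key=(r,))` (counter-based: any
repetition is reproducible in isolation and results are independent of
execution order), draws a fresh 6 000-patient sample, computes sample
truths, and fits the roster — strategy effects D2→X4, D2→X5 (short only,
clustered), perception effects X4→T1, X5→T1 and treatment effect T1→Y2
(short and full): 8 estimates per repetition. Degenerate repetitions (for
example, a draw whose few implementing organizations make two
organization-level regressors collinear) are recorded and excluded, never
resampled — resampling would bias the study toward easy samples; more than
1% failures aborts the run as a misconfiguration signal. At the canonical
scale failures are rare (0–1 per 1000 repetitions).

Relative bias per repetition is (estimate − truth)/truth with the truth of
that repetition's own sample; the summary reports the mean across
repetitions, its empirical standard error (sample SD), and the 95% CI
`mean ± 1.96·SE/√R`. The mean of per-repetition ratios is the headline
aggregation; the ratio of means is reported as a secondary column. Zero
truths make relative bias undefined and raise an error pointing at the
coefficients. The default is R = 1000 (a desk-scale run of a few minutes);
R = 10000 is available by flag.

The organization-level estimands dominate the Monte Carlo noise: their
per-repetition relative-bias SD is ≈0.25 versus ≈0.04 for the
patient-level treatment effect, so at R = 1000 their mean relative bias is
measured with a standard error of ≈0.8 percentage points. A measured mean
near ±1% for those estimands is therefore not distinguishable from zero
bias, and their confidence intervals are correspondingly wide.

## What the synthetic generator does and does not show

The generator reproduces the features the estimation theory depends on:
the decision chain with selection, the multilevel hierarchy with
organization-level shocks in a practitioner variable, moderate confounding
on every estimand, probit-consistent decision errors, and effects defined
per sample. It does not emulate measurement error, non-normal or
heteroskedastic errors, informative cluster sizes, patient non-compliance,
interference, or feedback across implementation cycles. Passing tests
therefore demonstrate that the identification-plus-estimation pipeline is
correct under the stated model, not that any real implementation study
satisfies that model — on real data the DAG is an assumption to be argued,
and the certified adjustment sets are only as good as the graph.

## Numerical choices and degenerate inputs

* Deterministic lexicographic topological order everywhere (sampling,
  replay, serialization), so a seed fully determines a draw across
  platforms and hash seeds.
* Dataset bundles are plain CSV (+ JSON manifest) with values at 12
  significant digits; selection-missing cells are empty; error tables are
  included by default so a re-read bundle is fully replayable (latent
  values are rebuilt by re-running the equations with the stored errors).
* Collinearity detection: exact rank test on the design matrix, offending
  columns identified via the QR diagonal.
* A draw with zero implementing organizations is a valid dataset (all
  gated columns missing); estimation on it raises an eligibility error,
  and its sample truths are NaN.
* Non-finite structural indices (coefficient blow-up) raise a numeric
  error naming the equation.
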