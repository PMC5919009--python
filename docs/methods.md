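# Methods

This note records the statistical models the package implements, the
assumptions and numerical choices behind them, and what the synthetic
cohorts do and do not establish about real data.

## Study design being modeled

A nested case-control study: incident cancer cases drawn from prospective
cohorts, each matched to `controls_per_case` controls (default 2) on sex,
cohort, fasting status (exactly) and age (within a ±2-year caliper; the
caliper is an assumption, chosen small enough to reproduce the confounding
control of individual matching — real studies rarely publish theirs).
Cases carry one of three mutually exclusive tumor subtypes (KRAS-mutated,
BRAF-mutated, wild-type); the generator never produces double mutants.
Tumor mutation data can be made unavailable for a subset of cases through
a logistic model on case covariates, with the true subtype retained in a
hidden column for recovery testing.

## Synthetic cohort generator

**What it emulates.** 14 plasma one-carbon-metabolism biomarkers drawn
multivariate log-normal (default exchangeable correlation 0.25, with any
positive-definite matrix accepted); 17 SNPs drawn from Hardy-Weinberg
proportions ((1−q)², 2q(1−q), q²); a designated SNP multiplying its
metabolite's concentration by `snp_metabolite_effect` per allele (default
1.07 on cystathionine — the size of effect such panels report);
anthropometry, creatinine (for Cockcroft-Gault eGFR), neopterin, smoking,
alcohol and two 5-level physical-activity scales as background
covariates; case-only tumor stage, site, and age/year of diagnosis for
the availability model.

**Outcome mechanism.** Within each candidate set the subtype is drawn
first from `subtype_probs` (default 0.26 / 0.24 / 0.50, the subtype mix
such unselected Scandinavian case series report); the case is then the
member selected with probability proportional to
`exp(Σ_e β_{e,subtype} x_e)` — a within-set conditional logit. This is
exactly the model the conditional-likelihood estimators assume, so
parameter recovery is unbiased by construction rather than only
asymptotically. Biomarker effects are per 1 generating-SD of the log
concentration, which the control-based per-SD scaler converges to.

**Default effect sizes.** The default `effect_spec` gives the designated
SNP per-allele log-odds of (ln 0.72, ln 1.56, ln 0.94) for
(KRAS, BRAF, WT) — a realistic "opposite effects across subtypes"
pattern, and deliberately weak enough that the network stage ranks it
highly without necessarily passing the inclusion threshold, matching how
such signals behave in practice.

**Missingness.** Exposures are masked completely at random at
`missingness_rate` per variable (validated to [0, 0.03]). The default
0.003 makes a 31-exposure panel lose ≈9% of subjects to complete-case
exclusion — the loss fraction such panels typically report. Informative
missingness exists only in the tumor-data channel, where it is the point.

**Seeds.** One master seed is split into named, CRC-keyed substreams
(matching, biomarkers, genotypes, outcome, clinical, missingness), so any
single component can be regenerated in isolation and every pipeline run
is bit-reproducible.

## Preprocessing

Continuous exposures are discretized into tertiles whose cut-offs are
inverse-ECDF (type-1) empirical quantiles *of the controls only*; bins
are right-closed (a value equal to a cut-off stays in the lower group).
Any convention applied identically to cases and controls would do; this
one makes the worked example (controls 1…9 → cuts (3, 6) → equal thirds)
exact. Age uses control-based quartiles; eGFR and neopterin control-based
tertiles; BMI the bands <25, [25, 30), ≥30. SNPs are dominant-coded
(any variant allele) for the network stage and per-allele for regression.
Self-reported covariates get an explicit "missing" category; biomarker or
SNP missingness is handled by complete-case exclusion with exact drop
counts (total = retained + dropped always). The per-SD scale for odds
ratios is (log x − control log-mean)/control log-SD; log-scale
standardization is used because the biomarkers are right-skewed and
summarized on the log scale. Cockcroft-Gault clearance is
(140 − age)·weight/(72·creatinine[mg/dL]), ×0.85 for women; a µmol/L
variant divides by 88.4 (unit must be stated by the caller — data sets
differ).

## Network screening

The score of a DAG is decomposable: each node contributes its multinomial
log-likelihood given its parent configuration minus (r−1)·q free
parameters (r child levels, q parent configurations). By default q counts
the parent configurations *observed* in the data (configurations that
never occur carry no parameters); the full Cartesian count is available
(`penalty_configs="full"`). The penalty coefficient is 1 per parameter —
the "AIC" convention of discrete structure-learning software, equal to
standard AIC up to the factor −2, which cannot change any comparison.

Hill-climbing starts from the empty graph and greedily applies the
single-arc addition, deletion or reversal with the largest strict score
improvement, with a deterministic lexicographic tie-break, until no move
improves. Add/delete deltas are cached per directed pair and refreshed
only for nodes whose parent set changed, so an iteration costs O(p)
local-score evaluations. Acyclicity is enforced by reachability checks on
every addition/reversal and re-verified on the final graph.

Bootstrap model averaging draws same-size row resamples (individuals, not
matched sets — the network stage treats the table as flat, with the
matching factors included as nodes; set-level resampling is available),
learns a network on each, and records for every unordered pair the exact
fraction of replicates containing an arc in either direction (edge
confidence) plus the per-direction fractions for display. Edge confidence
is direction-agnostic because the screening question is association, not
orientation. Category levels are fixed by the full table, so resamples
that happen to miss a level score against the same parameter space.

**Inclusion threshold.** The ideal confidence distribution is a two-point
mixture: mass t at 0 (noise edges) and 1−t at 1 (true edges). t̂
minimizes the L1 distance between that step CDF and the empirical CDF of
the observed confidences — a weighted median of the empirical CDF levels,
taking the smallest minimizer on ties — and the threshold is the
empirical t̂-quantile. Edges are included when confidence is strictly
above it. For a degenerate single-atom input this yields all-or-none
inclusion (none, by the strict inequality).

**Calibration caveat.** The empirical network retains spurious edges at
the AIC false-positive rate (an arc between independent binary variables
is added when the likelihood gain exceeds 1, asymptotic probability
P(χ²₁ > 2) ≈ 0.157), and because the bootstrap re-tests the *same*
empirical dependence, noise edges acquire confidences of roughly 0.3–0.5
rather than ≈0. The threshold therefore separates noise from signal well
when genuinely strong edges exist to anchor the mixture's upper atom (in
study-sized cohorts it lands near 0.5, and under a null outcome ≈90% of
exposures stay below it), but it is not a formal error-rate guarantee: an
occasional null exposure will exceed it. The pipeline treats the ranking
as a screen, not a test — which is also why the follow-up stage exists.

## Matched-set models

The conditional logistic likelihood
`Σ_s w_s [η_case(s) − log Σ_{i∈s} exp(η_i)]` eliminates set-level
nuisance parameters (the matching factors). Maximization is damped
Newton: analytic gradient and Hessian computed segment-wise over sets,
step-halving (up to 30 halvings) on likelihood decrease, convergence when
the gradient ∞-norm < 1e-8, observed-information standard errors, and a
sandwich (set-level score) covariance option. At β = 0 the log-likelihood
equals Σ_s log(1/m_s) exactly, which the tests use as a closed form.
Complete separation is reported (naming the runaway coefficient) when any
coefficient passes 15 in absolute value — far beyond any plausible
log-odds ratio — before the vanishing gradient could masquerade as
convergence. Weights enter per set via the case's weight; zero-weight
sets contribute nothing, and unit weights reproduce the unweighted fit to
machine precision.

Subtype-specific fits run one conditional logit per subtype on the sets
whose case has that subtype (controls travel with their case); sets whose
case lacks tumor data are excluded. By default biomarker models adjust
for BMI, smoking, alcohol, neopterin and both physical-activity scales by
regression, while SNP models rely on the matched-set conditioning alone —
genotypes are not confounded by lifestyle. The heterogeneity LRT compares
subtype-specific exposure coefficients against a common coefficient, with
nuisance covariates subtype-specific in both models so the test isolates
the exposure (with that choice the full model factorizes into the
per-subtype fits, which the implementation exploits); a shared-nuisance
variant is available. df = #subtypes − 1; p from the χ² upper tail.
Cochran's Q across cohort-specific estimates uses inverse-variance
weights. The SNP-metabolite association is OLS of log concentration on
allele count, reported as 100·(exp(slope) − 1) percent per allele.

## Selection-bias weighting

Availability of tumor data among cases is modeled by maximum-likelihood
logistic regression on tumor stage, site, age and year of diagnosis,
cohort and sex (configurable). Weights: controls 1, cases with tumor data
1/p_i, cases without 0; cases missing availability-model covariates are
excluded and counted. The weighted conditional logit is consistent when
availability depends only on the modeled covariates — verified in the
tests by a constructed-bias simulation in which tumor site depends on the
exposure genotype and availability on site: the unweighted complete-case
estimates are displaced by the derivative of log-availability in the
genotype while IPW restores the truth. Model-based SEs are the default
(mirroring how such analyses are usually reported); sandwich SEs are
available, and are the principled choice under weighting. The balance
check refits the availability model weighted by 1/p_i (available) and
1/(1−p_i) (unavailable) via a binomial GLM with frequency weights; under
a correct model all covariate coefficients are null (reported with a
default p > 0.2 reading). Weight truncation is not applied.

## Case-case analysis

Baseline-category multinomial logit of subtype on exposure with wild-type
as reference; exponentiated slopes are RORs, asymptotically equal to the
ratio of subtype-specific case-control ORs (the consistency report
quantifies the log-scale difference against its joint SE). No covariate
adjustment by default. The primary heterogeneity test is the 2-df LRT of
both slopes against zero — subtype composition unrelated to the exposure —
matching the single p-value such tables print; a 1-df equal-slopes LRT
(fitted by constrained optimization) is also provided since the printed p
could reflect either formulation.

## Pipeline

simulate → preprocess → bootstrap-averaged network → outcome ranking →
conditional-logistic follow-up of the exposures above the threshold (or
the single top-ranked exposure when none passes — the screen-then-test
logic still needs a candidate) → IPW sensitivity analysis (when any case
lacks tumor data) → case-case replication. Every stage writes delimited
text; the manifest records the config hash, master and per-stage seeds,
row counts in/out per stage, and library versions. Identical config and
seed give byte-identical numeric outputs (the manifest timestamp is the
only field that differs). The Bonferroni display threshold is
α/#exposures (0.05/31 ≈ 0.002 for the default panel).

## Problem sizes used in tests and the acceptance script

Type-I-error calibration of both heterogeneity LRTs uses 1000 null
replicates at 240 matched sets / 360 cases — small enough to run in
seconds each, large enough for the χ² asymptotics to hold. Parameter
recovery runs at 3000–4000 cases (3-SE criteria); the acceptance script
recovers the subtype ORs at 40 000 cases, the SNP-metabolite effect at
120 000 subjects, and the case-case RORs at 50 000 cases, so that
Monte-Carlo error is a small fraction of each estimate.
Network examples use 3–10 variables where exhaustive enumeration (25
DAGs on 3 nodes) is available as an oracle; study-scale checks (≈45
nodes, ≈1300 rows) use 40 bootstrap replicates.

## Known limitations

- The generator's covariates are mutually independent given the matching
  variables (no lifestyle-biomarker confounding unless configured), its
  biomarker correlation is exchangeable by default, and measurement error
  beyond log-normal noise is not simulated; passing recovery tests shows
  the estimators are correct under the assumed design, not that any real
  data meet those assumptions.
- The AIC-based network screen has no finite-sample error-rate control
  (see the calibration caveat above); its output is a ranking.
- The heterogeneity LRT relies on χ² asymptotics; with very few sets per
  subtype the calibration degrades.
- Conditional-logit separation is reported, not penalized; exact or
  Firth-type corrections are out of scope.
- No imputation: missing exposures are complete-case (regression stages)
  or explicit-category (self-reported covariates) only.
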