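# Methods

## Task geometry and conventions

The data model assumes the free-field localization protocol: 19 loudspeakers
at −90°…+90° azimuth in 10° steps, responses restricted to the same range,
15 repetitions per speaker for implant listeners (10 for normal-hearing
controls). Negative angles are the listener's left, positive the right, and
the grid is stored ascending; the protocol descriptions never fix a sign
convention, so this one is documented rather than assumed. Validation
requires every subject to cover the full grid with equal repetitions per
angle, which makes the overall RMS error exactly reconstructible from the
per-angle values (`overall² = mean(per-angle²)`).

## RMS error and its log transform

Per-angle RMS is the root mean square of (response − target) over the
repetitions at that angle; the overall RMS pools all trials. For the mixed
model the per-angle values are natural-log transformed. A per-angle RMS of
exactly zero (possible only in synthetic data) is replaced by 10⁻³ degrees
before the log, with a warning.

## Localization sensitivity index

For each unordered pair of target angles the two response samples are
compared with the tie-corrected Kruskal–Wallis statistic, using the
asymptotic χ²(1) reference even at n = 15 per group — that is the named
statistic, and a seeded Monte-Carlo permutation reference is available as an
option for small samples. The p-value maps to z = Φ⁻¹(1 − p) floored at 0
(the "positive z-score"); the LSI is the mean z over the 171 pairs. The
floor guarantees positivity and makes a null pair contribute ≈ 0.4 on
average rather than a negative value. Whether the index's original
formulation used a one- or two-sided p is not recoverable from the
description; a `two_sided` convention (z = Φ⁻¹(1 − p/2)) is selectable and
shifts the index's absolute scale upward without changing how it orders
listeners, so published absolute LSI values can only be matched under the
original convention. Ties are handled by the standard correction, since
touchscreen responses can repeat exactly.

## Four-parameter logistic fits

The localization function is modeled as y = β + (α−β)·S((μ−x)/σ) with
S the standard sigmoid: α is the right-most (upper) asymptote, β the
left-most, μ the midpoint and σ the slope parameter, negative for curves
that rise left-to-right (σ = −50 is near-identity over this grid). Fitting
is bounded nonlinear least squares (trust-region reflective) on raw trials —
the residual term indexes repetitions, implying trial-level fitting — from
the fixed start (90, −90, 0, −50) with α, β, μ ∈ [−90, 90] and
σ ∈ [−100, 100]; tolerances are 10⁻⁸ on parameters and cost with at most
1000 function evaluations, values the protocol leaves open. There are no
random restarts by default (a single stated initialization; an optional
multistart flag exists for robustness studies) and optimizer failure is
reported via a `converged` flag, never an exception. Because swapping
α↔β while negating σ leaves the curve unchanged, fits are canonicalized to
α ≥ β. The reported features are the response range α−β (≈180° for good
localizers) and σ.

## Pattern categories and the synthetic-data generator

The 20 categories cross 5 mean shapes (Ideal, Flat, Compressed, BiasedLeft,
BiasedRight) with 4 SD shapes (Ideal, LargerLateral, LargerLeft,
LargerRight). The parametric defaults are this package's own, chosen once to
reproduce the qualitative shapes and the control-vs-implant contrast, and
all are config-overridable:

- Ideal mean: identity. Flat mean: constant 0.
- Compressed mean: the 4PL form with asymptotes ±40°.
- Biased means: the full-range (±90°) 4PL shifted by ±35°, clipped at ±90°.
- The sigmoid mean shapes use slope parameter −30. This brings the
  Compressed curve to ~90% of its asymptote by the grid edge, so the shape
  visibly flattens laterally and its asymptotes stay identifiable when the
  4PL is fit back to simulated trials; at shallower slopes (e.g. −50) the
  curve never approaches its asymptote inside ±90° and the fitted range is
  ill-determined.
- Ideal SD: constant 8°. LargerLateral: 8° + 0.30·|a|. LargerLeft/Right:
  8° + 0.30·max(0, ∓a).

A simulated trial at angle a is Normal(mean(a), sd(a)) **clipped** (not
truncated-renormalized) to ±90°, the simplest censoring model for the
touchscreen's response bound. Clipping has two visible consequences the
tests account for: boundary-angle means are biased inward by ≈ sd·φ(0), and
for Biased means saturated at ±90° the censored side's observed SD is
attenuated, which makes, e.g., BiasedLeft×LargerLateral and
BiasedLeft×LargerRight genuinely confusable — the dominant source of the
residual few-percent misclassification. What the generator does not emulate:
front–back confusions, attention lapses, response-grid quantization,
session effects, or listener-idiosyncratic slopes (every simulated listener
of a mean shape shares that shape's slope). Passing tests therefore certify
the machinery on clipped-Gaussian response patterns, not the full richness
of real BiCI data.

Seeding: every cohort draws one base seed from the master generator and
seeds each category's subjects from (base, CRC32 of category label), so a
fixed master seed reproduces a cohort bit-identically and the registration
order of categories is immaterial.

## The bootstrap + PAM classifier

One listener at a time is clustered jointly with 1000 simulated subjects
(50 per category, 15 repetitions per angle — the experiment's own design) on
the 38-dimensional feature vector of per-angle means and SDs. Distances are
Euclidean on the raw features — means and SDs share degree units, so no
standardization by default (a z-scoring switch exists). Simulated subjects'
features are recomputed from their simulated trials, the stricter reading of
"bootstrapping", not taken from the analytic category curves.

PAM is the classical deterministic BUILD + SWAP k-medoids on the full
distance matrix: BUILD seeds greedily (ties in the gain go to the
highest-index candidate, matching the reference R implementation's scan
order), SWAP applies the steepest single (medoid, non-medoid) exchange until
none improves, so the cost trace is strictly decreasing and the result is a
certified single-swap local optimum. All swap deltas of a pass are evaluated
in O(n²) via nearest/second-nearest-medoid bookkeeping — algebraically
identical to evaluating every classical swap, fast enough to rerun hundreds
of times. On unstructured point clouds BUILD+SWAP (like R's `cluster::pam`,
which returns identical costs on such instances) can stop short of the
global optimum; on data with actual cluster structure it is exact in
every tested instance.

The listener's label is the modal true category among the simulated members
of its cluster. Mode ties go to the tied category whose in-cluster members
have the smallest mean distance to the listener; a listener alone in its
cluster gets the label `unclassifiable-singleton` with a warning. The
procedure repeats 50 times (default) with freshly simulated cohorts; the
final category is the histogram mode, ties resolved by the
highest-numbered tied run and then lexicographically. Because PAM itself is
deterministic, run-to-run variability comes only from the fresh reference
cohorts — which is exactly what the reliability histogram is meant to
measure.

The "ideal SDs" margin used in group contrasts collapses the 20 categories
by SD shape alone (any mean shape), and symmetrically for means; contingency
tables are ordered (late, early) × (ideal, other).

## Mixed model and Satterthwaite degrees of freedom

The per-angle log-RMS model is a linear mixed model with fixed effects
OD (onset group, 0 = early ≤ 5 y, 1 = late — the coding that makes a
negative OD coefficient mean lower error for late onset), STA = target
angle² (0…8100 deg²), their interaction, and a random intercept per
listener; REML by default, ML for AIC-based comparisons. Estimation is
delegated to `statsmodels.MixedLM` with internal column rescaling (STA's
range otherwise ill-conditions the solver). Since statsmodels reports only
large-sample z tests, the Satterthwaite step is computed here: with
θ = (σ²_between, σ²_within) and f(θ) = Var(β̂ᵢ) from the profiled GLS
covariance, df = 2f²/(gᵀAg) where g is the finite-difference gradient of f
and A the inverse observed information of the profiled REML log-likelihood
(closed form per subject block via Woodbury). On a balanced 48 × 19 design
this yields ≈ n_subjects-scale df for between-subject terms and ≈ 862 for
within-subject slopes; the implementation agrees with lme4/lmerTest to four
significant figures in an oracle test. A between-subject variance below
10⁻³ of the residual variance is reported as 0 with a boundary warning
(the analogue of lme4's singular-fit flag).

Backward stepwise selection removes, at each step, the term whose deletion
most lowers AIC, never removing a main effect while an interaction contains
it; mixed-family comparisons use ML fits and the winner is refit with REML.
Factor pairs flagged by the |r| > .75 collinearity screen may not enter the
same selection. Note the statistical fact (encoded in a test): AIC's
2-point penalty retains a pure-noise predictor with asymptotic probability
P(χ²₁ > 2) ≈ 0.157, so "the noise term is dropped" holds at a ~84% rate,
not near-certainty.

## Chi-square and power

Category-membership contrasts use the uncorrected Pearson chi-square on the
2×2 table (df = 1); a zero margin is an error. Power is estimated by
simulation: each replicate draws the two group counts binomially at the
observed rates (1/16 and 12/32 by default, with the observed group sizes —
"equal sample size to that obtained" read as the same sizes), tests the
resulting table at α = .05, and counts zero-margin tables as non-rejections;
10,000 replicates give a Monte-Carlo SE of ≈ 0.005 near power 0.7.

## Regression cohorts for parameter recovery

`simulate_regression_cohort` generates per-angle log-RMS tables from the
random-intercept model at specified coefficients (defaulting to the
published point estimates: 3.339, −0.401, 3.626×10⁻⁵, 3.668×10⁻⁵) with a
16:32 early:late split. The default variance components
σ_between = 0.31, σ_within = 0.43 (log-RMS units) are back-derived
analytically from the published coefficient standard errors — 0.101 for OD
via Var ≈ (σ²_b + σ²_e/19)(1/16 + 1/32), and 9.21×10⁻⁶ for STA via
σ_e/√(16·Σ(a²−3000)²) — so simulated cohorts mimic the study's information
content. Two open points in the source description are noted without
resolution: derived patient durations use the ages as given (the onset ages
are printed rounded to 6 months; whether durations used rounded or raw ages
is unstated), and the early-group lateral increase is reported from the
coefficients (3.626×10⁻⁵ × 8100 ≈ 0.294 log units) although the narrative
mentions 0.239.

## Problem sizes in the shipped tests

The suite favors sizes that exercise every code path at high statistical
power per second: classifier recovery runs 20 subjects per category at 10
classification runs × 10 reference subjects per category (the full 50 × 50
protocol is the library default); interval coverage uses 200 simulated
48-listener cohorts; PAM is checked against exhaustive medoid search on 100
small instances and against R's `cluster::pam` as an independent oracle.
Missing-data policy throughout: derived factors stay undefined when inputs
are absent (no imputation), and regressions use complete cases.

## Known limitations

- The generator's category parameterizations are stand-ins chosen by this
  package; a study-faithful reimplementation of the original simulation
  appendix could swap them (and the clipped-Gaussian noise model) via
  `make_category` params without touching the classifier.
- The LSI's absolute scale depends on the p→z convention (above).
- PAM guarantees a single-swap local optimum, not a global one; reliability
  across bootstrap cohorts, not restarts, is the intended safeguard.
- Satterthwaite df are implemented for the random-intercept structure only.
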