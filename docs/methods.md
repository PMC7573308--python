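# Methods

This note documents the models, defaults and numerical choices behind
metabonet, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Phenotype definitions

Hyperuricemia is serum uric acid ≥ 420 µmol/L (men) / ≥ 360 µmol/L (women),
inclusive at the cut-off. BMI classes use the Chinese adult criteria
(18.5 / 24 / 28 kg/m²) with half-open bins; below 18.5 is labelled
`excluded` and dropped from phenotype-stratified output, because the six
phenotypes are defined only from normal weight upward. Metabolic health
uses four ATP-III components — elevated blood pressure (SBP ≥ 130 or
DBP ≥ 85 mmHg or antihypertensive drugs), elevated triglycerides
(≥ 1.7 mmol/L or lipid-lowering drugs), elevated fasting glucose
(≥ 5.6 mmol/L or diabetes medication), reduced HDL-C (< 1.04 / 1.3 mmol/L
men/women) — with waist circumference excluded for collinearity with BMI.

**Unhealthy at ≥ 2 components.** The source criteria can be read as "more
than two" abnormalities; standard ATP-III usage once waist is dropped makes
two components the unhealthy boundary, and that convention is the default
here (`Thresholds.unhealthy_min_components = 2`, configurable to 3).

**VAI.** The sensitivity definition of metabolic health uses the published
sex-specific Visceral Adiposity Index — men
`(WC/(39.68 + 1.88·BMI))·(TG/1.03)·(1.31/HDL)`, women
`(WC/(36.58 + 1.89·BMI))·(TG/0.81)·(1.52/HDL)` — healthy strictly below
1.59. Abdominal-obesity cut-offs (90 / 80 cm) are the common Asian waist
criteria and are config-overridable, as the source tables do not print
them. All threshold comparisons happen at full floating precision.

## Synthetic cohort generator

The generator is phenotype-first: sex (53.6% female), then the six-way
phenotype from the published sex-specific distribution, then raw
measurements drawn *conditionally on the label* — BMI from a truncated
normal inside the phenotype's BMI class, an ATP-III component count drawn
given health status (healthy: 0 with prob 0.55, 1 with 0.45; unhealthy:
2/3/4 with 0.55/0.30/0.15), component membership weighted by the published
sex-specific component prevalences, and each component measurement drawn
from a truncated normal on the correct side of its cut-off. Drug flags are
only ever set where the matching measurement already trips the component.
Consequence: re-deriving phenotypes from the raw columns reproduces the
generating labels exactly, so calibration targets survive the full
derivation path.

Serum uric acid follows a sex-specific log-normal (strictly positive,
right-skewed; scale σ = 0.30 / 0.28 log-units for men/women, giving
coefficients of variation near the published marginal ones) whose location
varies by (phenotype, sex). `calibrate_prevalence` sets the location by
bisection so the analytic tail mass above the sex threshold equals any
target prevalence (the tail is strictly increasing in location; brackets
are found by doubling, at most 100 times; targets of exactly 0 or 1 are
rejected). The default spec calibrates all twelve strata to the published
prevalence table (men 11.4–39.4%, women 4.0–30.7%).

For odds-ratio recovery the generator can instead draw hyperuricemia from
an explicit logistic model — `logit P = logit(p₀) + β_phenotype +
Σ β_c (x_c − ref_c)` — and then draw uric acid from the stratum law
truncated to the matching side of the threshold. Because every generating
covariate appears in the fitted adjustment set, the fully adjusted refit is
correctly specified and consistent for the generating log-odds.

Free covariates (age, height, lipids, insulin, hs-CRP, white cells,
behavioral flags) use truncated normals / log-normals / Bernoullis loosely
matched to the published sex-specific moments; no quantitative claim
depends on their exact values. Seeding is stream-split per field (master
seed + CRC32 of the field name), so adding or reordering columns never
perturbs other columns.

**What the generator does not emulate:** the survey's multistage cluster
sampling, household structure and weights; within-subject correlation
between uric acid and the continuous covariates beyond what phenotype
membership induces; measurement error and digit preference; missing data
(tables are complete by construction). Passing recovery tests therefore
demonstrates correctness of the estimators under the calibrated marginal
and conditional structure, not robustness to real-survey artifacts.

## Epidemiological estimators

Prevalence intervals default to Wilson score (good small-sample coverage
and asymmetric bounds; Clopper–Pearson available), with the bounds clamped
to exactly 0/1 when k = 0 or k = n. Descriptives use pooled-variance
Student t-tests and uncorrected Pearson chi-square tests. Logistic models
are fitted by Newton iteration (IRLS) through statsmodels with covariance
from the inverse observed information; convergence requires max |score|
< 1e-8 within 50 iterations, and coefficient magnitudes above 20 are
flagged as (quasi-)separation rather than reported. Odds-ratio intervals
are Wald on the log scale (`exp(β̂ ± z·SE)`), the standard reporting choice
and the one matching intervals that are symmetric on the log scale. Age
enters the models as a continuous term; age groups are used only in
descriptives and network coding. Stepwise selection is backward
elimination by AIC with the five phenotype indicators entering and leaving
as a block (the phenotype is one construct, not five), ties broken by the
given term order.

## Bayesian-network machinery

**Data representation.** Discrete tables are compressed to unique row
patterns with multiplicities; a bootstrap resample of n rows with
replacement is then exactly a multinomial redraw of the pattern weights,
which makes several hundred resamples cheap even at n in the tens of
thousands.

**Score.** Decomposable BIC with natural logs,
`Σ_jk N_ijk ln(N_ijk/N_ij·) − (ln N)/2 · q (r − 1)` per node, `0·ln 0 = 0`,
higher is better. Family scores are cached per (node, parent set) within a
dataset.

**Search.** Tabu search over single-arc add/delete/reverse moves, scanned
in lexicographic (source, target, move-type) order for determinism; moves
violating acyclicity or the blacklist, or removing whitelist arcs, are
never proposed. The best admissible neighbour is accepted even when it
worsens the score; the undoing move is tabu for 10 iterations unless it
would beat the incumbent (aspiration). The search starts from the
whitelist-only graph and stops after 50 consecutive non-improving accepted
moves (or 500 iterations). Optional restarts perturb the start with random
admissible arcs; the single deterministic run is the default. Acyclicity
of candidate moves is checked by depth-first path search.

**Layering.** Roles (outcome / exposure / demographic / covariate)
generate the blacklist: no arc may leave the outcome, and the two
exposure-layer readings of metabolic state (syndrome flag and BMI level)
may not explain each other. Pointing at the outcome is *permitted*, not
forced: the whitelist is empty by default, with forcing available through
`ConstraintSet(whitelist=...)` for users who want the stronger reading.

**Averaging.** Arc strength is the fraction of R bootstrap networks
containing the arc in either direction (granularity 1/R; R = 300 by
default); direction is the orientation fraction among those. The consensus
keeps pairs with strength ≥ 0.5 (0.85 for the simplified view), orients by
majority (ties toward the lexicographically smaller source), and — because
thresholded majority orientations can cycle — drops the weakest arcs until
acyclic.

**Parameters and inference.** CPTs are relative frequencies with optional
pseudo-count α (default 0, i.e. MLE; α = 1 for Laplace; an unobserved
parent configuration under α = 0 gets a uniform row with a warning). Exact
queries multiply the CPTs into the full joint tensor and condition by
slicing — with ≤ 15 nodes of ≤ 5 levels the state space stays well under
10⁶ cells, so enumeration is fast and easy to verify; likelihood weighting
provides an independent Monte-Carlo cross-check with a reported
self-normalised importance-sampling standard error.

**Network coding.** The cohort network uses 14 variables: sex, age group
(3 levels), BMI level (3), ATP-III metabolic syndrome (binary),
hyperuricemia, diabetes, smoking, alcohol, urban residence, abdominal
obesity, and LDL-C / total cholesterol / hs-CRP dichotomised at 3.37 / 5.2
/ 3.0 (mmol/L, mmol/L, mg/L) with white blood cells at the cohort median;
all cut points are configurable. The *reasoning* variant replaces the
binary syndrome flag with the 0–4 component count (scenarios condition on
specific counts, which a binary flag cannot express); its structure is
carried over from the averaged network and its CPTs refitted on the
recoded data.

## Reference ground truths

The five-node reasoning network (sex, BMI group, component count, diabetes,
hyperuricemia) encodes the reported conditional probabilities of
hyperuricemia; its root marginals (BMI 0.40/0.30/0.30; counts
0.28/0.18/0.16/0.14/0.24; diabetes rising from 5% to 50% with the count)
were chosen so every queried evidence cell holds a few thousand expected
records per 100,000 samples, making ±0.01 recovery achievable at that n.
Where the reported values distinguish sex (obese, zero components: 0.076
men / 0.124 women) the CPT is sex-specific, and where they distinguish
diabetes (obese, four components: 0.606 with, 0.514 without, mixing to the
reported 0.56) it is diabetes-specific; elsewhere rows are shared. The
six-node structure-recovery network mixes a chain, a fork and a collider
with 0.85/0.15-style conditionals strong enough that the skeleton is
identifiable at n = 20,000.

## Problem sizes in the validation studies

The test suite runs each study at a size chosen to make its tolerance a
≥ 3-sigma statement where possible: stratum-prevalence calibration at
n = 200,000 (4 binomial SDs), conditional-probability recovery at
n = 100,000 (±0.01), odds-ratio recovery at n = 200,000 (±0.10 around
OR 1.95), structure recovery over 100 replicates of n = 20,000 with R = 100
bootstraps, Wilson coverage over 10,000 replicates at n = 142, and
null-effect odds-ratio coverage over 100 cohorts of n = 5,000. The
CPT round-trip invariant uses a three-node chain whose parent
configurations are all well occupied; networks with rare parent
configurations need proportionally more samples for a uniform ±0.01 bound.

## Known limitations

- Exact inference enumerates the joint; beyond ~20 binary-equivalent nodes
  a junction tree or variable elimination would be required.
- Wald intervals and MLE CPTs are first-order tools; very sparse strata
  (few events) deserve profile-likelihood or shrinkage approaches.
- The averaged network is a consensus of point estimates, not an
  equivalence-class (CPDAG) object; arcs whose direction is not identified
  from data are resolved by bootstrap majority and, failing that,
  lexicographic order.
- Generated cohorts are complete-case by construction; the reader stage
  drops incomplete rows but no imputation machinery is provided.
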