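# Methods

## Scope and data model

`methclocks` analyzes beta-value matrices (methylation fraction per CpG
probe and sample, in [0, 1]) as exported from 450K-style arrays, together
with a sample sheet linking samples to subjects, tissue roles
(tumor / adjacent normal / blood), case-control groups, tumor stage, age
and sex. Raw IDAT intensity files are out of scope: the package ingests
beta matrices only, optionally with a same-shaped matrix of detection
p-values. Missing entries are held as NaN; since NaN is never a valid
beta value it functions as an explicit mask, and every computation (means,
ranks, quantile normalization) is defined over observed entries only.

## Quality filtering

Filtering is two-step, in the order masking → removal:

1. every entry with detection p-value strictly above `p_threshold`
   (default 0.01) is masked as missing;
2. every probe whose missing fraction is then strictly above
   `missing_threshold` (default 0.05) is removed.

Both inequalities are strict, so a probe with exactly 5 % missing entries
is retained. When no detection p-values are present the first step is
skipped and reported as such. The published filtering sentence is
ambiguous between this mask-then-remove reading and a harsher
probe-level one; the alternative — drop a probe outright if *any* sample
fails detection or the probe exceeds the missingness threshold — is
available as `mode="any_sample"`.

## Stratified quantile normalization

Quantile normalization is applied independently within probe categories.
On a real 450K manifest the six categories are the design-type ×
color-channel split; for synthetic data without a manifest, probes are
hashed into six pseudo-categories (`hash_categories`), which exercises the
stratified code path with a deterministic, order-independent assignment.

Within a category, each sample's observed values are replaced by a common
reference distribution at their rank positions. The reference is the
across-sample mean of per-sample quantile functions evaluated on a common
grid; with complete data this reduces to the classic "mean of order
statistics" construction, and every sample's within-category value multiset
becomes identical. Ties receive the mean of the reference values their
rank positions span; missing entries are excluded from ranking and stay
missing. With incomplete data, each sample's quantile function is linearly
interpolated onto the grid (the convention used by mainstream
normalization code for arrays with missing entries, restated
format-agnostically).

A deliberate deviation from intensity-level pipelines: the original
CPACOR procedure normalizes *intensities* before computing betas. This
package ingests betas, so it normalizes beta values per category instead.
The stratification logic — the step that matters for probe-type bias — is
preserved; control-probe PCA adjustment is not included.

Normalization is fit/transform shaped: `fit` learns the per-category
reference from one matrix, `transform` maps any matrix onto it, and
`fit_transform` is the classic batch operation.

## Clock scoring

`ClockScorer` computes `score = intercept + Σ_j w_j β_j` over a
coefficient set. The bundled MRscore set carries the ten published CpG
weights as decimal strings (converted once at load, so golden tests are
bit-stable), intercept 0, identity transform. Missing clock CpGs are
handled by policy:

* `error` — abort, naming the probe and sample;
* `mean_impute` (default, with a warning) — substitute the probe's mean
  over non-missing samples, learned in `fit`; a probe with no observed
  value anywhere (including probes absent from the matrix) cannot be
  mean-imputed and raises;
* `skip_renormalize` — drop the term and rescale the remaining weights so
  the total absolute weight Σ|w| is preserved; this is the policy to use
  when upstream filtering may remove clock CpGs outright.

The published studies do not state how missing clock CpGs were handled
after filtering; mean imputation is the least-surprising default for
near-complete data.

### PhenoAge-style transformation

Phenotypic-age clocks map the linear predictor to years in two steps: a
Gompertz-CDF conversion to a mortality probability over a fixed horizon,
then a log-log rescaling to the age scale,

    risk = 1 − exp(−exp(lp) · C),  C = (exp(γ·t) − 1) / γ
    age  = a₀ + log(−a₁ · log(1 − risk)) / b.

Composed analytically this is affine in the predictor,
`age = a₀ + (log a₁ + log C + lp) / b`, and that closed form is what the
code evaluates: the literal two-step underflows (`log(1 − risk)` hits
`log 0`) once `exp(lp)·C` exceeds ~745. Constants arrive via
`#transform.*` headers in the coefficient file; defaults are the identity
parameterization (slope 1, offset 0, unit Gompertz scale). Monotonicity
is verified on a grid at load, and invalid constant combinations (a
non-positive argument to a logarithm, zero slope) are rejected naming the
offending constant. The multitissue clock's under-20 log-linear age
calibration is available as a third transform type (`horvath`,
`adult_age` default 20) but not exercised by default; its coefficients
are an external input.

## Age acceleration

`AgeAccelerationRegressor` fits `DNAmAge = a + b·age` by the closed form
`b = cov(age, DNAmAge)/var(age)` and returns residuals. Samples without a
known age are excluded and logged; all-equal ages make the slope
undefined and raise. Residuals sum to zero and are orthogonal to age by
the normal equations, which the tests verify to 1e-8.

## Paired comparison

Tumor/normal pairing is by subject: a subject contributes at most one
sample per role (enforced at sample-sheet validation), subjects missing
either role or either value are excluded and counted. The Wilcoxon
signed-rank test drops zero differences (the classic convention; Pratt's
treatment is available), ranks |d| with midranks, and takes W as the sum
of positive-difference ranks.

The exact two-sided p-value doubles the smaller tail of the exact null
distribution, capped at 1. The null distribution is computed by the
generating-function recursion over doubled midranks (doubling makes every
achievable statistic an integer, so tail counts are exact integers); this
enumerates exactly the 2^n equally likely sign assignments and is checked
against a literal brute-force enumeration in the tests. Exact mode is
guarded at n = 25 (2^25 ≈ 3·10^7 assignments); `auto` uses the exact
distribution when n ≤ 25 and |d| is tie-free, otherwise a normal
approximation with tie-corrected variance
`n(n+1)(2n+1)/24 − Σ(t³−t)/48` and a 0.5 continuity correction toward the
mean. Two-sided testing is used throughout (the direction of tissue
differences varies by cancer type, so a one-sided choice would be
arbitrary).

Stage-stratified comparisons run the same test within each stage; strata
with fewer than two informative pairs are skipped and logged rather than
raising.

## Discrimination

The AUC is the Mann–Whitney statistic with ties counted one half, which
equals the trapezoidal integral of the ROC curve swept over all distinct
thresholds (asserted to 1e-12 on every result). "AUC derived from
logistic regression" is honored in the monotone-invariance sense: a
univariate logistic fit (Newton iterations, capped at 25 — under complete
separation the likelihood has no maximum but the predicted ordering is
already determined) runs alongside, and its linear-predictor AUC must
equal the score AUC (or its complement when the fitted slope is
negative). The rank is taken on the linear predictor rather than the
predicted probability to avoid float saturation of the logistic function
under strong separation.

Confidence intervals default to DeLong's variance estimator (midrank
placements), truncated to [0, 1]; a Wald interval on the logit-AUC scale
is the alternative. The paired origin of tumor/normal samples is ignored
in the CI, matching the unpaired ROC treatment this style of analysis
uses; for strongly correlated pairs the DeLong interval is conservative
in some regimes and anti-conservative in others, so paired designs should
read the CI as approximate. Scores that discriminate in the "wrong"
direction (e.g. a mortality score that is *lower* in prostate tumor
tissue) can be reported with `flip_orientation`/`oriented`, which maps
AUC to 1 − AUC and records the flip.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
per probe j and subject i:

    logit(β) = logit(m_j) + u_ij + δ_j·[tumor/case] + ε

with baseline `m_j ~ Beta(α, β)` drawn once per probe (defaults α = β = 2,
a broad unimodal beta-value distribution), subject effect
`u_ij ~ N(0, subject_sd²)` shared by both samples of a subject (default
0.5, giving within-pair correlations in the range reported for repeated
methylation measurements), configured logit-scale shifts δ_j in tumor or
case samples, and entry-level noise `ε ~ N(0, noise_sd²)` (default 0.3).
The logit-normal form keeps values strictly inside (0, 1) with no
clipping and makes additive effect sizes well-defined. Stage is assigned
uniformly and independently of effects; ages are uniform over 55–75
years, the recruitment range of the emulated blood study. Detection
p-values, when requested, flag a configured fraction of entries above the
0.01 threshold. The paired design defaults to a balanced case/control
split (cases = ⌊n/2⌋), so 187 subjects reproduce the emulated study's
93 cases and 94 controls.

What the generator does **not** emulate: probe-type-specific intensity
distributions, chip/batch effects, cell-type composition, age-dependent
drift, or correlation between neighboring CpGs. Passing tests therefore
demonstrate the correctness of the statistical machinery under the stated
generative model, not performance on real arrays.

A single integer seeds each generator run; the two designs draw from
distinct streams so paired and case/control data generated under the same
seed are independent.

## Problem sizes and numerical conventions

Simulation-based tests use 40–300 subjects, 30–240 probes, and 10 seeds
for Monte-Carlo direction/recovery checks; the null rejection rate of the
exact signed-rank test is estimated from 2000 replicates at 20 pairs, and
DeLong CI coverage from 1000 replicates at 100 + 100 samples — sizes at
which the binomial error bands in the assertions are meaningful while the
whole suite runs in seconds. Exact worked examples (the bundled weights,
hand-computed quantile normalization, constructed OLS residuals) are
asserted at 1e-9–1e-12; Monte-Carlo quantities at 3 standard errors.
Ranks use midranks everywhere; sorting is stable; the exact-test guard,
thresholds and strict inequalities are as stated above.

## Known limitations

* Beta-level (not intensity-level) normalization, as discussed.
* No multiple-testing adjustment across cancers or clocks (none is
  applied in the emulated analysis style).
* The logistic fit is a consistency check, not a reported model; its
  coefficients are not exposed.
* DeLong CIs ignore pairing (see above).
* Whether clock scores should be computed before or after normalization
  is not determined by the emulated analyses; the pipeline scores after
  normalization by default with `preprocess.skip_normalization` to
  bypass.
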