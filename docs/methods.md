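# Methods

`abratio` analyses the plasma amyloid-β 42/40 ratio as a blood biomarker of
brain amyloid pathology, with a focus on one question: does an
Asp(1)-specific detection antibody (which sees only Aβ species starting at
the canonical N-terminal aspartate, e.g. 3D6) yield a larger measurable
contrast between amyloid-positive and amyloid-negative subjects than an
N-terminus-agnostic antibody (e.g. 6E10)?  This note documents the models,
the statistical procedures, the synthetic-data generator, and the design
choices that were genuinely open.

## The two-compartment dilution model

Circulating plasma Aβ is modelled as a mixture of a CNS-derived pool
(fraction `f_cns` of the total) and a peripherally derived pool
(`1 − f_cns`).  Assumptions:

1. amyloid pathology lowers the Aβ42/40 ratio of the CNS pool only — the
   peripheral pool is unaffected;
2. CSF Aβ is essentially all Asp(1); the relative CSF ratio reduction in
   amyloid-positive subjects is `r_csf`;
3. a fraction `f_ntx` of the *peripheral* plasma pool carries an N-terminus
   other than Asp(1) and is invisible to an Asp(1)-specific assay.

The measurable relative plasma ratio decrease is the CSF decrease scaled by
the CNS share of the *detected* pool:

    decrease(agnostic) = f_cns · r_csf
    decrease(Asp1)     = f_cns / (1 − f_ntx·(1 − f_cns)) · r_csf

Defaults `f_cns = 0.30`, `f_ntx = 0.30`, `r_csf = 0.50` (dimensionless
fractions): the CNS share rises from 30% to 30/79 ≈ 38% under Asp(1)
detection, and the predicted decreases are 15.0% vs 18.99%.  `f_cns` is the
midpoint of isotope-labeling/arteriovenous-difference estimates (30–50%
range, conservatively held at its lower end), `f_ntx` the upper end of the
20–30% ballpark from 2D-Western-blot surveys of plasma Aβ N-termini, and
`r_csf` the canonical ~50% CSF reduction.  `f_ntx` has no within-package
calibration and is exposed as a free parameter; the `sensitivity_grid`
helper maps predictions over ranges of all three parameters.

Two rounding modes exist because the conventional back-of-the-envelope
presentation of the model rounds the detected CNS fraction to two decimals
before multiplying (0.38 × 50% = 19%).  `exact` (default) carries full
precision (18.99%); `two_decimal` reproduces the rounded arithmetic.
`worked_example(total_ng, params)` emits the full mass budget (at 100 ng:
30 ng CNS + 70 ng peripheral, 21 ng excluded, 79 ng detected) and enforces
conservation of mass exactly.

The model treats the Aβ40 and Aβ42 families as one pool when computing the
detected CNS share; this is justified by the empirical observation that
Aβ40 levels do not differ by amyloid status, so the ratio contrast is
driven by the 42 numerator alone.

## Synthetic cohort generator

No subject-level data are deposited for this study design, so every
downstream stage is validated against a generator whose defaults *are* the
study conditions:

* groups of 37 amyloid-negative / 36 amyloid-positive subjects (73 total;
  78 with `n_neg=40, n_pos=38` for QC fixtures);
* CSF agnostic ratio drawn from the group's normal component — negative
  0.082 ± 0.0055, positive 0.033 ± 0.0056 — truncated to (0, 1); the two
  components sit ~9 component-sds apart, so the bimodality is unambiguous;
* CSF Asp1 ratio = agnostic ratio × 1.20 (the observed inter-antibody
  calibration offset, ≈ 0.100/0.083) with 2% lognormal jitter; CSF Aβ40
  lognormal (log-mean 8.74, log-sd 0.37, i.e. median ≈ 6.3 ng/mL with ~39%
  CV); Aβ42 = ratio × Aβ40;
* plasma ratios: amyloid-negative agnostic mean 0.077; Asp1/agnostic scale
  1.44 (≈ 0.111/0.077); amyloid-positive means reduced by the dilution
  model's *exact* predictions for the respective detection mode, so the
  generator's ground truth is definitionally consistent with the forward
  model (15.0% and 18.99% at the defaults);
* between-subject plasma-ratio variation: a lognormal latent shared by both
  read-outs (6.5% relative sd) plus assay-independent jitter (2%).  With
  the technical component below this reproduces a total ratio spread of
  ~10.5% relative, matching the observed robust spread (MAD/median ≈
  0.008/0.077) and implying Cohen's d ≈ 1.5 (agnostic) / 1.8 (Asp1) —
  consistent with published effect sizes for this design;
* duplicate technical reads: two independent lognormal multiplicative
  errors per analyte calibrated so sd/mean ≈ `replicate_cv_pct` (default
  8%; only the 20% exclusion bound is reported for the reference assay, the
  operating CV is this package's choice).  At 8% a duplicate pair exceeds
  the 20% CV bound by chance with probability ≈ 1.2%, so a realistic
  cohort loses a few subjects to QC, as real plates do.  QC-logic fixtures
  use 3%, where chance exclusions are negligible (~2 × 10⁻¹¹ per pair) and
  injected violations are provably the only exclusions;
* injectable QC defects: `inject_qc_violations` spreads one analyte's
  duplicate pair to a target CV (default 40%) for a chosen number of
  subjects and deletes one plasma read for others, deterministically under
  a seed;
* covariates (age, sex, ApoE4 carriage, t-Tau, pTau181 with left-censoring
  at 15.6 pg/mL) are drawn from group-typical distributions for schema
  completeness only and never influence the analytes — the analysis never
  adjusts for them.

What the generator does **not** emulate: plate/run structure and drift,
calibration-curve back-calculation, dilution-factor arithmetic, skewed or
heavy-tailed biological outliers, and any covariate–analyte dependence.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated distributional model, not robustness to real
pre-analytical artefacts.

Plasma IP-eluate levels are *relative* concentrations (immunoprecipitation
recovery is unknown); all conclusions rest on ratios, which are invariant
to the unknown recovery factor.

## Quality control

A subject is excluded when any analyte's duplicate CV is **strictly
greater** than 20% (the bound is quoted as "> 20%", so exactly 20.0% is
retained) or when any analyte has fewer than two finite reads
(`require_duplicates=True`).  The CV uses the sample (n−1) standard
deviation — for duplicates, |a−b|/√2 over the mean — matching common
assay-QC practice; the denominator convention is not externally fixed, so
it is documented here.  A singleton in *any* analyte excludes the subject
(a conservative generalization; the motivating case had singletons in two
plasma analytes).  Each analyte's duplicate pair is treated as one run;
run-level repetition structure is not modelled.

## Mixture-model dichotomization

Subjects are classified amyloid-positive/negative from the CSF agnostic
42/40 ratio alone.  A two-component univariate normal mixture is fitted by
EM (tol 1e-8 relative log-likelihood, max 1000 iterations, log-likelihood
asserted nondecreasing each iteration).  Initialization is deterministic —
split at the sample median, moment-match each half — plus five seeded
random restarts keeping the best likelihood, so the fit is reproducible
under its seed.  Component collapse (vanishing weight or sd) raises a
diagnostic error rather than returning a silent degenerate fit.

The decision threshold is the intersection of the two weighted component
densities between the means, solved in closed form (the log-density
equation is quadratic; the root inside the open interval between the means
is taken) and cross-checked in tests against a dense-grid/bisection
oracle.  Classification is `value ≤ τ → positive` — the boundary belongs
to the positive class.  The published threshold for this cohort design
(0.058) arises from clinical data that are not deposited; synthetic
recovery (component means within 3 SE, threshold vs oracle to 1e-6) is the
verifiable property.

## Effect statistics

For a marker x with amyloid-positive group P and negative group N:

* relative median difference (%) = 100·(median P − median N)/median N;
* relative mean difference (%) analogously;
* Cohen's d = (mean P − mean N)/pooled sd, pooled over (n₁+n₂−2) degrees
  of freedom, without Hedges small-sample correction (the default of the
  commonly used effect-size implementation);
* robust summaries: median and MAD scaled by 1.4826;
* group comparisons: two-tailed Mann–Whitney (exact when n₁+n₂ ≤ 16 and
  tie-free, otherwise the tie- and continuity-corrected normal
  approximation, via scipy).

Contrasts are always positive-minus-negative, so informative plasma
markers have negative values; magnitudes are compared as |d|.  Per-subject
analyte values are the mean of the duplicate reads.  Summary-table
p-values are intentionally not multiplicity-adjusted (exploratory
convention), which is stated in the table metadata rather than corrected.

## .632 bootstrap comparison of the two read-outs

The two plasma ratios are paired within subject, so the difference of
their effect sizes is tested by resampling subjects with replacement and
recomputing *both* metrics on the *same* resampled subjects.  Defaults:
1000 replicates, stratified resampling (within each amyloid group,
preserving group sizes — effect metrics need both groups in every
replicate; a pooled mode exists for sensitivity analysis).  Each replicate
difference d_b is combined with the observed difference d_obs by Efron's
.632 weighting, c_b = 0.632·d_b + 0.368·d_obs.

A normal distribution is fitted to the combined estimates: mean = sample
mean of c_b; **sd = the combined spread re-normalized by 1/0.632**, which
equals the spread of the raw replicate differences and is the bootstrap
estimate of the sampling SE of d_obs.  This re-normalization is essential:
the .632 weighting shrinks the spread of the combined estimates by the
factor 0.632, and using that shrunken sd directly would understate the SE
and inflate the one-sided type-I error from the nominal 0.05 to roughly
0.30.  With the re-normalized sd the test holds its level, which the
acceptance suite verifies by simulation (200 null cohorts generated with
`f_ntx = 0`, where both read-outs share the same true contrast; the
rejection rate must fall inside the binomial 95% CI around 0.05).  The
calibration simulation uses the relative-mean-difference metric, whose
bootstrap SE is the best behaved of the three at n = 73.

P-values are normal tail probabilities at zero.  The primary alternative
is directional (`less`): the working hypothesis says the Asp(1)-specific
contrast is *more negative*.  `greater` and `two_sided` are always
reported alongside.  A Shapiro–Wilk p-value on the combined estimates is
attached as a diagnostic of the normal approximation; it never gates the
result.  Degenerate cases (identical markers, zero replicate spread)
return p = 1 with an explicit flag; replicates that degenerate under
`cohens_d` are redrawn, and more than 10% redraws is an error.

Statistical power under the default study conditions is worth stating
plainly: at n = 37/36 with true contrasts 15% vs 19%, simulation puts the
one-sided power at α = 0.05 near 0.58 for the mean-difference metric but
only ~0.38 (median) and ~0.42 (Cohen's d).  The observed difference points
the expected way in ~90% of seeds for all three metrics.  A single cohort
of this size is thus adequately powered only for the mean-based comparison.

## ROC and DeLong

Plasma ratios are lower in amyloid-positive subjects, so the default score
orientation is `lower_is_positive` (scores negated internally), making
AUC > 0.5 for informative markers.  The AUC uses the rank-sum identity
with ties counting ½ and is asserted equal to the trapezoidal area of the
explicit curve.  Paired AUCs are compared with DeLong's placement-value
covariance test (midrank implementation; two-sided normal p), validated
in tests against the R `pROC` implementation and against a simulated null
where its p-values must be uniform.  Threshold-level classification
statistics (sensitivity, specificity, PPV, NPV, accuracy, Youden J) default
to the Youden-optimal threshold — the rule is pluggable and recorded,
since no external convention fixes it — with threshold ties classified
positive, mirroring the CSF `≤ τ` convention.

## Association

Pearson correlations on concentrations are computed after log2 transform;
42/40 ratios are left untransformed in the matrix view by default
(heatmap convention) and can be log2-transformed via the `all_log2` preset
(pairwise-scatter convention) — the two presets exist because both
conventions are in common use and they answer slightly different
questions.  Method-comparison lines between the two read-outs use Deming
regression with λ (ratio of y- to x-error variance) defaulting to 1, the
standard choice when both assays have comparable noise; the closed-form
slope satisfies the axis-swap identity at λ = 1 and tends to the OLS slope
(λ→∞) or inverse reverse-OLS slope (λ→0) in the limits, which the tests
check at λ = 10⁶/10⁻⁶.  Point estimates only; no jackknife standard
errors.

## Pipeline and reproducibility

`run_pipeline` executes QC → dichotomization → group summaries → effect
metrics → bootstrap (all three metrics) → ROC/DeLong → association →
dilution-model context, recording each stage's output or its failure
reason (dependent stages are skipped, independent ones still run).  One
global seed derives per-stage seeds by hashing the stage name, so any
stage re-run in isolation reproduces its in-pipeline result; the JSON
report (canonical key order, 6 significant digits) is byte-identical under
the same config and seed, and embeds the config hash, package version and
seed.  A cohort table round-trips losslessly through the delimited-text
writer/reader, including left-censored covariates serialized as
`<floor` strings.

## Problem sizes used in validation

Simulation-based checks run at deliberately modest sizes chosen to give
stable Monte-Carlo verdicts: contrast recovery averages 100 cohorts of
n = 73; bootstrap calibration uses 200 null cohorts × 1000 replicates;
mixture recovery uses 500 draws; the DeLong null uses 500 simulations of
n = 50.  Monte-Carlo tolerances are stated in the tests themselves (2–3
standard errors, binomial CIs, KS at α = 0.01).

## Known limitations

* The dilution model is a deliberate simplification: no kinetics, no
  blood–brain-barrier transport modelling, no inverse fitting of the
  compartment parameters to data.
* Generator defaults for plasma between-subject variances are
  reconstructed from robust summaries (MADs), not reported variances.
* The headline clinical-cohort numbers (−20.86%/−15.56% median contrasts,
  d 1.73/1.48, AUC 0.875/0.884, τ = 0.058) cannot be regenerated without
  the original subject-level data; the package validates the machinery by
  synthetic recovery and oracle equivalence instead.
* Exact sidedness and stratification of the original bootstrap procedure
  are not externally specified; both are explicit, logged options here.
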