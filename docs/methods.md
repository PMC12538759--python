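# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic-cohort tests do and do not show.

## Instrument scoring

SF-36 subscales follow the RAND 36-Item Health Survey 1.0 recode-and-
average rules; the item→0–100 recode table and subscale membership ship as
a versioned JSON data file (`data/sf36_rand_v1.json`) so the scoring
constants are auditable and replaceable without code changes. A subscale
is the mean of its answered items and is undefined when more than half its
items are missing (the standard half-scale rule). PCS/MCS are norm-based:
subscales are z-scored against the 1990 US general-population means/SDs
and combined with the published orthogonal factor-score coefficients
(`data/sf36_norms_1990.json`), then rescaled to mean 50 / SD 10. The
responder rule's ±2-point PCS threshold presupposes this norm-based
metric. Note the component coefficients were derived for the original
(Ware) subscale scoring, which differs slightly from RAND scoring for
bodily pain and general health; we apply them to RAND subscales, a common
and documented approximation.

MFI-20 domains are sums of four 1–5 items after reverse-keying the ten
positively phrased items (`data/mfi20_key.json`); there is no published
half-scale rule for the MFI, so partial forms are treated as missing
rather than prorated. BAS and SSS are validated pass-throughs (decade grid
0–100; integer 0–10).

## Responder rules

Thresholds are implemented exactly as published, inclusive/strict as
written, and exposed as a `Thresholds` dataclass (the published values are
the defaults; alternative MCID sets are configuration, not defaults). Two
totalization decisions were needed:

- *Single responder rating.* The published overall rule does not cover
  "exactly one responder rating and no partial ratings"; we classify it
  overall partial responder, preserving the responder > partial > non
  ordering and making the map total.
- *Missing instruments.* An instrument without both endpoints is
  `not_evaluable` and contributes nothing to the overall rule (absence of
  evidence); a participant with no evaluable instrument is routed to
  model prediction.
- *BAS gap.* ΔBAS in (0, 10) is unreachable on the decade grid; pre-scored
  inputs that land there are classified non-responder with a warning.

One consequence of keeping the strict `−10 < ΔMFI-aggregate < 0` window
verbatim: with exactly one improved domain, an aggregate change of −9 is
partial responder while −10 is non-responder. The rule is therefore not
monotone at that single boundary; we implement it as written and pin the
behaviour in a test rather than "repairing" it.

## Imputation

Missing feature values are filled by single imputation on the participant
× (timepoint : feature) matrix for the ten model features at all four
timepoints, jointly over rule-labeled and unlabeled participants. Chained
equations (scikit-learn's `IterativeImputer`: round-robin Bayesian-ridge
regressions, mean initialization, ≤10 iterations, tolerance 1e-3 on the
standardized scale) are the default; kNN (k = 5, 10; scaled Euclidean
distance on mutually observed standardized features) is the comparator.
Imputation runs on standardized columns, never touches observed cells,
clips imputed values to each feature's scale bounds, and is deterministic
given its seed. Grid features (BAS decades) are imputed continuously; only
rule-based stratification sees snapped values, the model consumes
continuous differentials. One completed table is produced per seed; Rubin-
style pooling across imputations is deliberately out of scope.

Known limitation: regression imputation predicts conditional means, so the
imputed T3 values of late dropouts are shrunk toward the cohort-mean
trajectory — item quantization acts as measurement error on the interim
values and attenuates the extrapolation (classical errors-in-variables).
Model predictions for non-completers inherit this bias toward the majority
class; this mirrors what any single-imputation + classifier workflow does
with monotone dropout and is visible in the synthetic-truth comparisons.

## Responder model

Features are z-scored (training statistics only) and fit with a softmax
multinomial logistic regression, L2 penalty with inverse strength C = 1
(the penalty family and solver are fixed by the workflow being
implemented; the strength is not published, so the conventional default is
exposed in `ModelConfig`). Cross-validation is repeated stratified k-fold
(3 splits × 5 repeats); the scaler is re-fit inside each training fold, so
reported CV metrics contain no test-fold leakage — a deliberate choice
where a single pre-scaled pipeline would be ambiguous. Confusion matrices,
per-class precision/recall/F1, and calibration bins aggregate over all
out-of-fold predictions.

Coefficients are reported per class in the symmetric (sum-to-zero)
parameterization — one β per class per feature, interpretable as "this
class vs the rest", matching how one odds ratio per class is usually
quoted — with Wald CIs from the ridge-penalized observed information. A
reference-class parameterization with unpenalized Wald inference (verified
against `statsmodels.MNLogit` to ~1e-5 in the SEs) and a seeded percentile
bootstrap (default B = 2000) are available; bootstrap is the automatic
fallback when the information matrix is singular, which is how quasi-
separation manifests — affected CIs are flagged `unstable` rather than
reported as infinite bounds. OR CIs are exact exponentials of β CIs.

Feature selection fits an L1 model (saga solver) and keeps features with
any coefficient |β| > 1e-8 across classes; the default lasso strength
(C = 0.2) keeps roughly half the ten features at the trial's sample size.
Ties in predicted probability are broken by the fixed class order
non_responder < partial_responder < responder, for reproducibility.

## Longitudinal statistics

Each outcome is modeled with a participant random intercept and fixed
timepoint effects, fitted by REML (statsmodels MixedLM; default optimizer
with a Powell fallback). On complete balanced data the Wald F of the time
effect coincides with classical repeated-measures ANOVA, and that case is
computed directly as the two-way OLS ANOVA. The F-test's degrees of
freedom are scaled by the Greenhouse-Geisser ε̂ computed from the
double-centered complete-case covariance (bounded in [1/(k−1), 1]); with
missing data this complete-case ε̂, and the equicorrelated ρ = ½ structure
used for Dunnett, are documented approximations to what commercial
packages do with their own unpublished details.

Dunnett many-to-one adjustment: paired mean changes vs baseline, with the
max-|t| distribution of k equicorrelated (ρ = ½) t variates evaluated by
seeded quasi-Monte Carlo integration of the multivariate-t rectangle
probability (error well below 1e-4); a single comparison degenerates
exactly to the paired t-test. Adjusted p-values are clipped into the
mathematically exact sandwich [p_raw, min(1, k·p_raw)], which only removes
quadrature noise. Simultaneous 95% CIs use the same critical point (found
by root-finding between the pointwise-t and Bonferroni bounds); the joint
df is the smallest paired n minus one, a conservative choice under
unbalanced missingness.

FDR control uses the canonical Benjamini-Krieger-Yekutieli two-stage
step-up: stage 1 is a linear step-up at α′ = α/(1+α); with r₁ rejections
and m̂₀ = m − r₁, stage 2 re-runs the step-up at α′·m/m̂₀. Rejections are
cross-checked against `statsmodels` `fdr_tsbky`. q-values are the monotone
adjusted p's of the operative stage and can be smaller than the raw p
(adaptive scaling) — this is a property of the procedure, not a bug. One
BKY pass is applied per analysis family (a figure panel: the family's time
effects plus all its Dunnett-adjusted comparisons), with family membership
configurable.

Biomarkers: concentrations (pg/mL) are log2-transformed; values at or
below a configured detection floor are replaced by floor/2 and flagged
(the floor defaults to 0, i.e. no substitution, and zero concentrations
without a floor are an error). Fold change per timepoint is 2^(mean paired
log2 difference) — the geometric-mean ratio. Associations between
baseline→T3 clinical differentials and biomarker log2 differentials use
Spearman's rs (average ranks for ties; exact permutation p for n ≤ 9, the
t-approximation otherwise) with a companion OLS slope/intercept. QQ tables
list ordered residuals of the additive participant+time model against
standard normal quantiles at positions (i − ½)/n.

## Synthetic cohort

The generator is first-class, tested code. Defaults emulate the trial's
structure: 86 treated participants; latent class mix ≈ 18/35/17 of 70
(non/partial/responder); interval dropout hazards (16/86, 15/70, 15/55)
reproducing the 86 → 70 → 55 → 40 attrition in expectation, optionally
class-weighted so "no benefit" dropouts concentrate among non-responders;
item-level MCAR missingness at 1%. Baseline scale locations put the cohort
where a moderately-to-severely affected ME/CFS population sits (BAS ≈
N(37, 15) decade-rounded, MFI domains ≈ 15, SF-36 subscales low, SSS ≈ 7).
Class mean T3 improvements are chosen so rule stratification of completers
lands near the trial's class mix and the descriptive changes (BAS up a few
points, MFI aggregate ≈ −6 to −8, PEM ≈ −2 to −3); interim timepoints
realize 40% / 75% of the T3 effect. Biomarker log2 shifts (BECLIN-1 up
≈1.3–1.5-fold by T2–T3; pSer258-ATG13 down beyond two-fold at T3) are
coupled to each participant's realized clinical improvement through a
Gaussian copula (|ρ| = 0.5) — the minimal structure that reproduces both
the marginal shifts and biomarker-clinical rank correlations.

Item vectors are sampled to score exactly to the latent targets for
MFI/BAS/SSS and within one recoded-item quantum (max item step ÷ item
count) for SF-36, so generator→scorer round-trips are testable. A
`well_separated_config` profile widens class margins and shrinks noise for
recovery tests.

What passing tests show: the scoring, rules, imputation, model, and
statistics compute what they claim on data with known truth. What they do
not show: real ME/CFS data have informative (non-MCAR) missingness,
response styles, floor/ceiling effects, and biomarker assay noise the
generator does not emulate; recovery rates on the synthetic cohort are not
estimates of clinical classification accuracy.

## Problem sizes

Default analyses run the n = 86 trial-shaped cohort; calibration
simulations use 1000 replicates (type-I error), 2000 replicates (FDR), a
10⁷-draw Monte-Carlo oracle (Dunnett), 200 replicates (Wald coverage), and
an n = 1000 cohort for end-to-end recovery — sizes at which the binomial
Monte-Carlo envelopes quoted in the tests are decisive.
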