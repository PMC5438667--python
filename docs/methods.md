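# Methods

`snpmeta` pools case-control association evidence for one biallelic SNP
from aggregate genotype counts.  This note records the statistical model,
the defaults and the judgement calls, in the order the pipeline runs them.

## Data model

Each study contributes genotype counts CC/CT/TT for cases and controls,
with C fixed as the reference allele and T as the risk allele; the reader
never re-orients alleles.  Ethnicity (Caucasian, Asian, African-American,
Mixed) and source of controls (hospital-based HB vs population-based PB)
are closed vocabularies; unicode dash variants in ethnicity labels are
normalised at parse time.  Newcastle-Ottawa stars ride along as metadata
and never enter a computation.  The bundled dataset is a 13-study
prostate-cancer collection for the MSMB promoter variant rs10993994
(31,584 cases, 30,251 controls).

## Genetic-model contrasts and per-study effects

Three contrasts collapse the genotype triple into a 2x2 table: allele
(T vs. C allele counts, two per person), dominant (CT+TT vs. CC) and
recessive (TT vs. CT+CC).  The homozygote contrast (TT vs. CC) is
deliberately not implemented.  Per-study effects are crude odds ratios
with the Woolf standard error sqrt(1/a + 1/b + 1/c + 1/d) on the log
scale — the form inverse-variance pooling requires.  If any cell is zero,
the Haldane-Anscombe correction adds 0.5 to all four cells (and only
then); the bundled dataset has no zero cells, so no correction touches
it.  A table whose exposed (or unexposed) column is empty in both groups
carries no odds-ratio information and raises an error rather than
returning an arbitrary value.  All 95% intervals use the fixed quantile
1.96.

## Heterogeneity and pooling

Cochran's Q uses fixed inverse-variance weights; I² = max(0, (Q-df)/Q)
with I² defined as 0 when Q = 0.  Between-study variance uses the
DerSimonian-Laird moment estimator τ² = max(0, (Q-df)/(S₁-S₂/S₁)),
truncated at zero, in which case the random-effects pool coincides with
the fixed-effect pool to machine precision (asserted at 1e-12).  The
fixed-effect estimator is inverse variance, not Mantel-Haenszel: it is
the estimator whose weights the DL procedure reuses.  Pooled inference is
z-based (no Knapp-Hartung).  Model choice follows the conventional
screen: random effects when p(Q) < 0.1 (strict) or I² > 50% (strict),
fixed effects otherwise.

## Subgroups and sensitivity

Subgroup analyses stratify by ethnicity and by source of controls, levels
reported in the canonical vocabulary order.  The default, and the
behaviour that reproduces the bundled dataset's published stratified
results, is `selection="inherit"`: the model chosen on the full study set
is carried into every stratum, as the classic stratified meta commands
do.  This mattered empirically — one stratum (allele contrast, PB
controls) is internally homogeneous (p_Q = 0.16, I² = 33) and would pool
fixed under per-stratum re-selection, giving a confidence interval
narrower than the stratified results this dataset is known for;
`selection="per-stratum"` remains available for the stricter convention.
A single-study stratum reports the study's own crude OR/CI exactly (a τ²
cannot be estimated from one study).  Leave-one-out sensitivity re-pools
each k-1 subset with the selection rule re-run per subset (every reduced
subset of the bundled data remains heterogeneous, so the two conventions
agree there); it requires k ≥ 3.

## Publication-bias tests

Egger's test is the classical unweighted OLS of the standardised effect
y/se on precision 1/se, intercept tested with t on k-2 df (the OLS fit
itself is delegated to statsmodels).  Begg's test follows the original
rank-correlation recipe: deviates from the fixed-effect mean are
variance-stabilised with v* = v - 1/Σw, Kendall's S is computed against
the variances, Var(S) carries the standard tie correction, and z uses the
(|S|-1) continuity correction.  Both need k ≥ 3.  On null synthetic
ensembles of 13 studies both tests reject at 4-5% at nominal 5%
(seeded Monte-Carlo, 1,000 replicates).

One property of the bias *mechanism* is worth recording: suppressing
studies with probability increasing in their one-sided z shifts every
retained standardised effect by the same constant, so the Egger intercept
is only estimable when the ensemble has a real precision spread.  The
power demonstration therefore uses the classic funnel ensemble — many
small studies plus a few large anchors — where strong suppression is
detected in ~70% of replicates; with uniformly small studies the same
suppression is nearly invisible to the test (power ~12-24%), which is a
property of the test, not a defect of the generator.

## Meta-regression

Moderators are dummy-coded against the first level observed in input
order.  Residual τ² uses the method-of-moments (DL-generalised) estimator
τ² = max(0, (Q_res - (k-p)) / tr(P)) with P the weighted projection
complement; coefficients are then fit by WLS with weights 1/(v+τ²) and
tested with z (fixed scale), plus an omnibus Wald test of all moderator
coefficients.  Method of moments was chosen over REML to keep the module
closed-form and to match the default lineage of the era's meta-regression
commands; the joint fit on the bundled data agrees with R's `metafor`
(`method="DL"`) to six decimals.  With no moderators the fit reduces
exactly to the DL pooled mean.  A factor with one observed level is an
error; a level observed in a single study warns and is retained.

## Power

Post-hoc power treats the pooled data as one 2x2 comparison: control
exposure frequency p0 (by default the pooled carrier fraction in
controls under the dominant contrast), implied case frequency
p1 = OR·p0/(1+p0(OR-1)), Woolf SE at expected cell counts, two-sided
normal approximation.  At OR = 1 the formula returns alpha exactly
(here the exact normal quantile is used, not 1.96, so that identity
holds).  On the bundled totals the power to detect OR 1.27 at
alpha = 0.05 is ≈1.000.

## Synthetic-data generator

Controls are multinomial draws from Hardy-Weinberg proportions at a
study-specific risk-allele frequency (default uniform on 0.30-0.45,
matching the bundled control frequencies); cases tilt those proportions
by (1, R, R²) under a multiplicative per-allele odds ratio R, so the
allele-model contrast recovers R asymptotically and the dominant and
recessive contrasts follow deterministically.  Between-study
heterogeneity is Normal(0, τ²) on the log per-allele OR.  Default sizes
(uniform 200-5,000 per arm) and moderator proportions mirror a typical
GWAS-era association literature; `fixture_like_scenario()` reuses the
bundled dataset's exact group sizes and moderator mix.  Each study has
its own counter-based stream seeded as `[seed, index]`, so ensembles are
bit-reproducible and extending an ensemble never perturbs earlier
studies.  Calibration under the null (seeded, 1,000 replicates each):
pooled-test type-I error 4.3%, HWE pass rate 95.6%; parameter recovery of
a per-allele OR of 1.3 at the bundled sizes shows |bias| < 0.001 on the
log scale over 500 replicates.

What the generator does not emulate: linkage disequilibrium, within-study
population stratification, covariate confounding, genotyping error, or
non-HWE controls.  Passing calibration tests therefore demonstrates the
estimators' behaviour under the model's own assumptions, not robustness
to those violations.

## Numerical and interface choices

Heterogeneity p is NaN for single-study pools (undefined, not 1).
Monomorphic control groups pass the HWE screen with χ² = 0 and a flag.
Relative pooled weights are normalised to sum to 1 (reported as % in
forest exports).  The report pipeline is deterministic: two runs on the
same input produce identical numeric content, and stages whose k
precondition fails (bias tests and leave-one-out below 3 studies,
meta-regression with too few studies) are skipped with explicit notes
rather than aborting.  The CLI prints ORs to 2 decimals and I² to 1
decimal, mirroring conventional reporting; the JSON report keeps full
precision.

## Known limitations

Only the three standard contrasts; no Mantel-Haenszel pooling on the
default path; no REML/Paule-Mandel τ², Knapp-Hartung intervals, or
prediction intervals; no trim-and-fill or Peters/Harbord bias tests; no
continuous moderators.  Crude (unadjusted) ORs only — the package pools
what aggregate genotype counts can support.
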