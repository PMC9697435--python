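# Methods

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic cohorts do and do not
emulate, and the design decisions taken where the field leaves options
open.

## Paired mixed ANOVA

The per-feature model is `Y_ijk = μ + Tissue_i + Person_j + ε_ijk` with
Tissue fixed, Person random, and i.i.d. Gaussian errors. Only complete
tumor/normal pairs enter a fit; unpaired samples and pairs with a missing
value are dropped (and counted) rather than imputed. With n pairs the
decomposition has mean squares MS_person (df n−1) and MS_error (df n−1),
and the method-of-moments (expected-mean-squares) equations are

    E[MS_person] = σ²_error + 2 σ²_person
    E[MS_error]  = σ²_error

solved exactly; a negative person-component solution is clamped to zero
and flagged (`VarianceComponents.clamped`), since a negative variance is
uninterpretable while the clamp only biases the estimate at the boundary.
On this balanced paired design the tissue F-statistic equals the square of
the paired t-statistic and the p-values agree to machine precision; the
test suite asserts this against `scipy.stats.ttest_rel` at 1e-10.

Degenerate features (zero residual variance, e.g. noise-free fixtures) are
reported with a `degenerate` flag and a boundary p-value (smallest positive
float if the effect is nonzero, 1.0 if it is zero) instead of NaN, so that
downstream FDR machinery never sees an invalid p. Features with fewer than
two complete pairs raise `InestimableFeatureError` with a reason code; the
whole-matrix drivers record the reason and continue.

## Signed fold change

A log2 effect e maps to `2^e` when e ≥ 0 and `−2^(−e)` when e < 0, so all
fold changes lie in (−∞,−1] ∪ [1,∞) and down-regulation reads as "−1.12 =
12% lower". Confidence limits are formed on the log2 scale
(`e ± t_{0.975,df}·se`) and mapped endpoint-wise; the map is monotone, so
ordering is preserved, and the antisymmetry `fc(−e) = −fc(e)` is exercised
by property tests. With df ≤ 0 the point estimate is kept and the interval
reported missing.

## Tissue × onset interaction

The interaction model is the two-way fixed-effects layout
`Y = μ + Tissue + Onset + Tissue×Onset + ε` with no person term, fitted as
cell means; the interaction F on a 2×2 layout is the squared interaction
contrast over its estimated variance with (1, N−4) df. Two consequences
are worth stating plainly:

* Under σ²_person = 0 the test is exact, and its type-I error at α = 0.05
  is verified to sit in [0.035, 0.065] over 2000 null features.
* Under σ²_person > 0 the residual absorbs the person variance while the
  paired-design interaction contrast actually cancels person effects, so
  the test is conservative and loses power relative to a person-adjusted
  interaction model. The package deliberately fits the person-free
  equation as specified for this pipeline and documents rather than
  "fixes" this; per-group paired fits (which do exploit pairing) carry the
  magnitude information in the two-column output.

Per-onset-group columns (fold change, CI, p) always come from the paired
model within each group, never from the unpaired cell means.

## Gene-set ANOVA

The set-level model `Y = μ + T + P + G + S(T*P) + ε` adds a fixed gene
effect G and a random sample effect S nested in tissue × person. Probes of
one gene are averaged on the log2 scale per sample before the model (the
chips carry several probes per gene; the model is declared at gene level).
Because S(T*P) has one level per sample, the tissue (and interaction)
contrast collapses exactly onto the per-sample mean of the member genes:
the implementation therefore fits the paired/interaction models to those
per-sample set means, which both equals the average of the member genes'
individual tissue effects and gives the correct sample-level denominator
df (samples, not gene × sample observations — the single biggest error a
naive long-table OLS would make here). Variance components for person,
sample and error are recovered by the method of moments using

    E[MS_error]  = σ²_e                      (gene × sample residual)
    E[MS_sample] = σ²_e + G σ²_S
    E[MS_person] = σ²_e + G σ²_S + 2G σ²_P

with the sample/person strata taken from the paired decomposition of the
set means (scaled by G). A single-gene set reduces exactly to that gene's
paired fit, which is tested. Genes absent from the chip are dropped and
counted in `n_genes_missing`; a set with no genes on the chip is an error
naming the missing symbols.

## Enrichment score

A category's over-representation among significant genes is the Pearson
chi-square (no continuity correction) on the 2×2 table
[in category vs not] × [significant genes vs remaining chip genes], and
the enrichment score is −log10(p). Base 10 was chosen because the
surrounding reporting style is 10^−x. Degenerate inputs (no significant
genes, category equal to the whole chip) are scored 0 with a flag rather
than erroring, since both occur routinely in scans over many categories.
The score is computed through the same `chi_square_test` as the clinical
module, so cross-module consistency is structural, not coincidental.

## Differential methylation and the five-class partition

Beta values are M/(M+U); M+U = 0 yields a missing value, never zero. No
cross-sample normalization is applied to beta values. Deep-sea loci
(> 4 kb from a CpG island) are excluded before testing. Within each onset
group every remaining locus gets the paired model; delta beta is the mean
within-person (tumor − normal) difference, so unpaired samples never
contribute. Benjamini–Hochberg q-values are computed within each onset
group separately (the two groups' DML lists are reported separately, so
pooling would answer a different question), and DML means q ≤ 0.05. The
interaction p comes from the person-free interaction model above, left
unadjusted at α = 0.05 — deliberately more liberal than the FDR-controlled
DML calls, favouring fidelity of the partition definition over stringency.

Classes: I (DML in both groups, interaction ns), II (both, interaction
significant), III (early-only, ns), IV (early-onset-specific: early-only
and significant), V (late-onset-specific), plus `locrc_only_ns` for
late-only/ns loci — unnamed in the original scheme but required for the
classes to partition every locus — and `not_dml`. The bookkeeping
invariants |I|+|II| = common DML and |III|+|IV| = early-only DML hold on
every dataset by construction and are asserted on simulated cohorts.

## Quantile normalization

Expression matrices are quantile-normalized across samples: the reference
distribution is the across-sample mean of sorted vectors; every sample is
mapped onto it rank-wise, ties receiving the mean of the reference values
at the tied ranks. Missing cells are excluded from ranking and restored as
missing; a sample with fewer observed values than the reference length is
mapped through interpolation on quantile positions. The transform is
idempotent (verified to 1e-12 on tie-free data) and no background
correction, detection-p filtering or beta-mixture normalization is
performed.

## Clinical statistics

Covariates are person attributes: each person counts once however many
samples they contribute. The chi-square is Pearson without Yates
correction — the uncorrected statistic is the one that reproduces the
published p-values from their printed counts (e.g. PNI 0.018 from
{90,8} vs {53,14}), which the regression suite checks row by row, and the
smallest expected cell count is reported so callers can judge validity.
The two-sample t-test from summary statistics offers pooled and Welch
variants, Welch by default. A published mean/SD t-test p of 0.180 for CEA
is not reproducible from the printed summaries under either variant
(≈0.12–0.15; plausibly missing values reduced the effective n), so it is
implemented but not used as a reference value.

## Synthetic cohorts

`SimulationConfig` defaults are the study conditions the pipeline was
designed around, chosen once:

* 67 early-onset and 98 late-onset persons, each with one tumor and one
  normal sample; an option drops a fraction of normals to exercise
  unbalanced handling (the motivating cohort had 71 tumors vs 70 normals
  on the expression chip).
* Expression: μ = 8.0 log2 units; tissue effect log2(1.09) on gene-set
  members with an extra log2(1.14/1.09) in the late-onset group (the
  headline replication-repair contrast magnitudes); σ_person = 1.0 and
  σ_error = 0.5 log2 units. The source study reports no variance
  magnitudes, so these were set for test power: σ_person ≈ 2σ_error makes
  the pairing advantage visible while keeping effects recoverable at
  cohort size.
* Methylation: baselines uniform on [0.2, 0.75]; common DML at |Δβ| = 0.2
  in both groups (alternating hyper/hypo), group-specific DML at
  |Δβ| = 0.08 — deliberately below the 0.1 magnitude line, as the
  early-onset-specific class is characterized by small deltas; noise and
  person effects on the logit scale (SD 0.25 each), back-transformed and
  clipped to [0.001, 0.999] to avoid truncation pile-up at 0/1; region
  classes drawn with the 450K chip's island:shore:shelf composition and a
  deep-sea fraction of 176112/485577.
* Clinical: category proportions per onset group taken from the published
  cross-tabulations; an exact-counts mode reproduces a requested table
  exactly (labels are shuffled within group so covariates are not
  artificially correlated).

Randomness comes from a single seed; expression, methylation and clinical
draws use sub-streams derived from stable named keys, so adding one
generator never perturbs another.

What the generator does **not** emulate: probe-level intensity chemistry,
batch/chip effects, copy-number contamination of beta values, correlated
features (loci/probes are independent given the person effect), or
realistic LD-like correlation between clinical covariates. Passing tests
therefore demonstrate correctness of the estimators and calibration under
the assumed model, not robustness to those real-data artifacts.

## Problem sizes in the test and acceptance runs

The validation suite uses cohorts scaled for precision of the check, not
for drama: 500 replicate features at 60 pairs/group for recovery and CI
coverage (binomial SE on 95% coverage ≈ 1%, so the [92%, 98%] band is a
3-sigma test), 2000 null features for the interaction type-I error
(SE ≈ 0.5%), and 2000 loci at 25–30 pairs/group for the partition checks.
The whole suite runs in well under a minute on one CPU.

## Known limitations

* Unbalanced designs are handled by restriction to complete pairs, not by
  Satterthwaite-type synthesis of denominators; with one sample of a pair
  missing the person simply drops out of that feature's fit.
* No REML/likelihood mixed models and no empirical-Bayes moderation of
  per-feature variances; at ≥ 60 pairs the moment estimators are adequate,
  at small n a limma-style approach would be more powerful.
* The interaction test inherits the conservativeness described above when
  person variance is large.
* Continuous covariates (e.g. raw CEA) are not modelled; they enter only
  through the summary-statistics t-test.
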