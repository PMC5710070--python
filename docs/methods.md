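# Methods

## The model

Weekly average daily feed intake of a growing pig is modelled as the sum of
population-level needs and animal-specific deviations. For animal *i* in
week *j*, batch *k* and pen *l*, with standardized covariates MW (metabolic
body weight, BW^0.75), WG (daily body-weight gain) and FG (daily backfat
gain):

```
y_ijkl = BA_jk + MW·β1j + WG·β2j + FG·β3j            (fixed)
       + b_l + MW·γ1jk + WG·γ2jk + FG·γ3jk           (pen, batch-week regressions)
       + a_1i + MW·a_2i + WG·a_3i + FG·a_4i          (additive genetic)
       + p_1i + MW·p_2i + WG·p_3i + FG·p_4i          (permanent environmental)
       + e_ijkl
```

The intercepts `a_1i`, `p_1i` measure consumption of feed beyond the
animal's needs — residual feed intake (RFI) — while the animal-specific
slopes measure the feed the animal allocates per sd unit of maintenance,
growth and fat deposition. Eight nested models differ only in which
covariates carry animal slopes (model 1: none, the classical RFI model;
model 8: all three). Per animal the effect vector has dimension
k = 1 + #slopes; across animals the genetic covariance is `G0 ⊗ A` (A the
pedigree numerator relationship matrix) and the permanent covariance
`P0 ⊗ I` over animals with records. Pen, batch-week regression and residual
effects are i.i.d. with scalar variances.

Covariates are standardized to mean 0, sd 1 within each week-by-batch cell
(sample sd, n−1), so slope effects are in g/d per covariate sd unit and
fixed regressions across weeks are directly comparable. Heritability of RFI
is defined at the covariate means (zero):
`h² = G0[1,1] / (G0[1,1] + P0[1,1] + σ²_pen + σ²_e)`; batch-week regression
variances are environmental context and never enter this denominator, at
any covariate value. Slope "heritabilities" are the additive share
`G0[j,j]/(G0[j,j]+P0[j,j])` of each component's individual variation.
Conditional parameters along covariate x use the quadratic form
`σ²_a(x) = G0[1,1] + 2x·G0[1,j] + x²·G0[j,j]` (permanent analogue alike),
with the other covariates held at 0.

## Data preparation

Raw inputs are daily intake (g/d; invalid feeder days coded missing),
sparse body-weight/backfat measurement events, and a batch/pen map. Missing
intake days are predicted from an animal-nested three-coefficient Legendre
polynomial fitted to the animal's observed days (age rescaled to [−1, 1]
over the animal's own range); body weight and backfat are interpolated by
the same construction to the first and last day of each age-week. Week *w*
spans days 7w..7w+6; endpoint gains divide by 7 d, and weekly MW is the
mean of the two endpoint weights raised to 0.75 (the weekly tables label MW
as the week's mean metabolic weight). Records are restricted to weeks
15–25 and to animals housed with at least seven pen mates, read as group
size ≥ 8 (configurable). Observed values are never altered by imputation,
and the pipeline is idempotent on its own output.

## Estimation

**Gibbs sampling.** Location effects have multivariate-normal full
conditionals and are updated in sweeps: single-site for scalar families
(class means, fixed regressions, pen, batch-week regressions) and blocked
per animal for the genetic and permanent k-vectors, maintaining the running
residual in place (numba kernels; ~1 ms per iteration at 3,500 records).
Variance components carry bounded-uniform priors over the valid space:
scalars then have scaled inverse chi-square full conditionals
(`SS/χ²_{q−2}`), and G0, P0 inverse-Wishart-form conditionals with degrees
of freedom q−k−1 (q = number of animal levels), which is exactly the flat-
prior posterior; draws outside configured bounds are rejected and redrawn.
Default protocol is desk-scale — 50,000 iterations, 10,000 burn-in,
thinning 10, 2 chains — chosen so a full model-8 analysis of ~3,500 records
runs in about a minute per chain; a long protocol (10⁶ iterations, 10⁵
burn-in, thin 100, 5 chains) is available through the same configuration.
Chains are merged before posterior summaries; the effective sample size
uses Geyer's initial-positive-sequence autocorrelation estimator, summed
over chains, and interval estimates are shortest 95% HPD intervals.

**DIC.** Model comparison uses the conditional deviance
`D = −2 log N(y | all location effects, σ²_e)`: DIC = mean(D) + p_D with
p_D = mean(D) − D(posterior means), matching common mixed-model MCMC
practice. Lower is better; on synthetic data generated from the full model
the full model beats the intercept-only model by margins that exceed
across-chain DIC spread.

**EM-REML and BLUP.** The mixed-model equations are assembled sparse
(genetic block `A⁻¹ ⊗ G0⁻¹`, animal-major). BLUP solutions use a direct
sparse factorization below 2,000 unknowns and Jacobi-preconditioned
conjugate gradients above (the coefficient matrix is SPD; pedigree
structure makes direct factorization fill-in prohibitive). EM-REML
alternates MME solutions with the classical expectation updates
`v ← (û'K⁻¹û + tr(K⁻¹C_uu))/q`, which require the dense inverse of the
coefficient matrix; it is therefore restricted to desk-scale systems
(default limit 2,500 unknowns). Its restricted likelihood is non-decreasing
across iterations, and estimates agree with balanced-design closed forms
and with Gibbs posterior means on synthetic data.

## Pedigree algebra

A is built by the tabular method; inbreeding by the Meuwissen–Luo
ancestor-traversal recursion (no dense A needed); A⁻¹ directly from
Henderson's rules with inbreeding-corrected Mendelian variances. Unknown
parents are unrelated founders; no genetic groups. Dense A is intended for
up to a few thousand animals; A⁻¹ is always assembled sparse.

## The synthetic-data generator

No public dataset exists for this kind of weekly feed-intake study, so
fixtures are generated with known truth. Covariate traits (standardized
MW/WG/FG) follow a multi-trait model — pen + additive + permanent effects
constant over weeks, plus a weekly residual — with the published 3×3
covariance blocks (the printed pen block is singular at printed precision
and is projected to the nearest usable covariance, eigenvalues floored at
10⁻⁴ of the largest). Feed intake follows the full model-8 structure with
week-varying fixed regressions (the published weekly coefficient profile),
batch-week intake means tracking the published weekly intake curve, and
the reconstructed variance components below. Default scale is 2 batches ×
160 animals in paternal half-sib families (4 offspring/dam, 4 dams/sire)
with 11 weekly records each, sized so that a fixture-plus-fit cycle runs in
minutes.

Two tracks exist. The weekly track emits analysis-ready records and is the
recovery fixture. The observational track additionally emits raw files:
growth curves are exact per-animal quadratics (so the Legendre
interpolation in preparation reproduces them exactly), measurement events
number 4–11 per animal, and daily intake is the weekly value plus day
noise re-centred within the week (weekly means round-trip exactly when no
days are missing). The raw-file covariates therefore come from quadratic
growth variation rather than from the multi-trait weekly model — a
deliberate simplification that keeps generation and preparation exactly
consistent end to end; the weekly track is the one that carries the full
covariance structure. What passing recovery tests show is that the
estimation machinery is correct under the model's own assumptions; they do
not certify behaviour under meal-validation artefacts, diet changes or
feeder faults, which the generator does not emulate.

### Recovery studies

Parameter-recovery runs size the fixture at the emulated study's scale —
4 batches × 250 = 1,000 recorded animals with 11 weekly records — and are
replicated over three independent fixtures, with posterior means averaged
across replicates. The replication matters because the slope variance
ratios G0[j,j]/(G0[j,j]+P0[j,j]) are weakly identified at this design: a
slope's total variance is a few hundred to a few thousand (g/d)² against a
~31,000 (g/d)² residual, the MW covariate is nearly constant within animal
(its weekly residual variance is 0.04 of a ~1 total, near-confounding the
MW slope with the intercept), and the genetic/permanent split rests on
between-family contrasts. Single-fixture posterior means of the backfat
slope ratio scatter with sd ≈ 0.07–0.10 even at 1,000 animals — in line
with the posterior sds of 0.14–0.20 that the original analysis reports for
these same ratios — while intercept heritability is recovered tightly.
A dual-route check (data generated exactly from the fitted design with
i.i.d. covariates versus the full fixture generator) recovers the
intercept heritability essentially exactly, and prior-free EM-REML point
estimates of the backfat slope ratio scatter as widely as the posterior
means — so the slope-ratio spread is information-theoretic, not a prior
artifact or an implementation defect. Recovery of the backfat slope's
additive share should therefore be read as a distribution centred near
(slightly below) its generating value with replicate-to-replicate spread
of several hundredths even after averaging, while intercept heritability
recovery is accurate to a few hundredths.

## Reconstructed generating components

The published analysis reports summaries, not the full (G0, P0) pair, so
the selection simulator rebuilds components that satisfy all printed
constraints simultaneously: intercept additive+permanent variance 21,010
(g/d)² (33,531 under the intercept-only model); intercept heritability
0.12 (0.18 intercept-only, where the additive intercept absorbs the
additive slope variance at unit covariate variance); slope additive shares
0.44/0.39/0.55; the published genetic correlation matrix; permanent
intercept–slope correlations (0.48, −0.79, −0.74) completed to a full
matrix by the one-factor rule r_jk = r_1j·r_1k. The total slope variance
(12,521) is allocated across MW/WG/FG proportionally to the squared fixed
regressions (235², 64², 33²) by default (equal split selectable), and the
environmental scale follows from the two heritability constraints with the
pen variance set to 5% of the residual: σ²_e ≈ 31,385, σ²_pen ≈ 1,569.
Every resolved number is returned in a provenance mapping and written next
to simulation outputs.

## The selection nucleus

120 sows, 30 boars; discrete generations. Each generation sows farrow two
parities (litter N(9, 6) rounded, truncated at 0); sows survive to the
second parity by a Weibull survival function (shape 2.0, scale 2.117 so
~80% survive one parity; the six-parity cap is retained but not binding
under full generational replacement). Matings avoid close relatives
(shared parent or parent–offspring, i.e. additive relationship ≥ 0.25 in a
non-inbred pedigree). Offspring survive lactation + growing with
probability 0.8, are penned in groups of 10, and all survivors of both
sexes are phenotyped for 11 weeks (~1,500 recorded candidates per
generation). Offspring breeding values are midparent plus Mendelian
sampling with covariance ½G0 (parental-inbreeding correction deliberately
omitted: pedigrees are three generations deep, making the correction
negligible). Six selection criteria rank candidates by −EBV of: the
intercept of an animal model without covariate regressions (FI), of the
intercept-only model (tRFI), of the full model (RFI), or of one of the
full model's slopes (FI/MW, FI/WG, FI/FG); a random-ranking null control
is available for testing. The best 120 females and the best male per sire
family become the next parents. Default evaluation solves the mixed-model
equations at the generating components (for the intercept-only criteria,
at the consistent intercept-only reduction); per-generation EM-REML
re-estimation is available for small configurations, where the dense
expectation step is affordable. Realized intensity is reported on the
female path on the trait scale (negative when selecting downward);
accuracy is the correlation of predicted with true effects over all
candidates; responses are per-generation changes in cohort means of true
genetic values, averaged over replicates.

## Numerical choices and degenerate inputs

Ties in truncation selection break by animal id. Cells with fewer than two
records, or zero spread, cannot be standardized and raise. Pedigree loops
and duplicate ids are rejected with the offending id named. Sampling
covariance scale matrices get a 10⁻¹⁰ relative ridge before the
inverse-Wishart draw; the fixed block of the MME gets a 10⁻⁸ ridge to
tolerate rank-deficient class layouts. PCG solves to relative residual
10⁻¹⁰. All randomness flows through seeded PCG64 generators; per-chain and
per-replicate seeds derive from one root seed via SeedSequence spawning,
so every result is reproducible from the manifest.

## Known limitations

Meal-level feeder validation is out of scope (inputs are daily intakes
with missingness already coded). Residual variance is homoscedastic across
weeks by design. Genomic relationships, genetic groups, maternal effects
and dominance are not modelled. Real-data posterior estimates cannot be
reproduced without the original records; simulation-based quantities
(selection intensity, selected proportions, evaluation accuracy, recovery
of the generating parameters) are the reproducible surface.
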