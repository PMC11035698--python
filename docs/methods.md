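# Methods

## Effect sizes

All effect sizes are natural-log response ratios computed from arm summary
statistics (mean, SD, n) of fully factorial OA × OW experiments. Individual
effects compare one stressor arm to the control; main (overall) effects
compare the pooled pair of arms containing a stressor to the pooled pair
lacking it, which measures the stressor's net effect averaged over the
other stressor's presence; the interaction effect is the difference between
the observed combined response and the additive expectation on the log
scale. Sampling variances are delta-method: each arm contributes
S²/(N·X̄²). The pooled-arm main effect uses the corresponding pooled-arm
form, `(X̄_a + X̄_b)⁻² (S_a²/N_a + S_b²/N_b)` per pair.

The individual effects are traditionally reported without a variance; we
attach the standard Hedges-type lnRR variance (the same per-arm terms as
the interaction variance) so that individual effects can carry CIs. No
small-sample bias correction is applied to lnRR. Group means must be
strictly positive; rows violating this (or n < 2, or out-of-range
latitudes) are excluded at ingestion and reported with row numbers rather
than patched with offsets, since an epsilon offset would make the log
ratio's value depend on an arbitrary constant.

Dispersion inputs may be SD, SE (`sd = se·√n`) or symmetric 95% CI
half-widths (`sd = half/1.96·√n`, the conventional z); asymmetric CIs are
rejected. Mortality is recoded as survival (1 − mortality, SD unchanged).
Trophic levels use the four-level vocabulary (primary producer, herbivore,
meso-predator, top-predator) with an optional merged "predator" level.
Climate regions from signed latitude: tropical |lat| ≤ 23.5°, subtropical
23.5–35°, temperate > 35° (polar observations are folded into temperate —
they are too few to support their own level). Boundary latitudes are
assigned equatorward; the original assignment convention at exactly 23.5°
or 35° is not documented anywhere we could find, and the ≤ convention is
the deterministic choice we fixed.

## Interaction orientation and classification

The raw interaction lnRR measures departure from additivity in the
response's own direction. To classify interactions irrespective of
direction, its sign is inverted when the additive expectation from the two
*individual* effects is negative: both individual effects negative, or
opposite signs with the negative one larger in absolute value. After
orientation, positive = amplification (synergism), negative = dampening
(antagonism).

"Crossing zero" is operationalized as the 95% Wald interval
(oriented value ± z₀.₉₇₅·√variance) containing zero. This CI criterion is
the prevailing convention in the multiple-stressor literature; a pure
sign-based rule would classify essentially no experiment as additive.
Exactly zero oriented values are additive by the same rule. Classification
is per observation (one interaction effect size per factorial response
record); frequency tables therefore count observations, and the
classification table carries cluster keys so users can reduce to one
representative per experiment if desired.

Chi-square tests of label × group independence are Pearson tests without
continuity correction (df = (r−1)(c−1)); a warning is emitted when any
expected count falls below 5.

## Multilevel model

Effect sizes are modeled as y ~ N(Xβ, M) with
M = V + Σ_t σ_t²·Z_tZ_tᵀ. V is the known sampling covariance:
block-diagonal over clusters (study × species × experiment — effect sizes
from the same organisms share a control arm), with off-diagonals
r·√(v_i v_j), r = 0.5 by default and 0.9 in the conservative sensitivity
variant. Random terms are categorical groupings (study, species, country,
author group); an effect-size-level term is always included to absorb
residual heterogeneity.

Estimation: variance components maximize the (restricted) Gaussian
log-likelihood over log σ² with L-BFGS-B (bounds on log σ² of [−30, 5],
relative tolerance 1e−10, two seeded random restarts plus a moment-based
start); β is the GLS solution at the optimum, with covariance
(XᵀM⁻¹X)⁻¹. Inference is Wald-z: symmetric 95% CIs and two-sided p-values,
no Knapp–Hartung adjustment — matching the symmetric-CI style of the
reported results. Q_M is a Wald chi-square on all non-intercept
coefficients (all coefficients in cell-means models); df equals the number
of tested coefficients. Random-structure and moderator selection use ML
AICs (REML likelihoods are not comparable across fixed-effect
specifications); reported fits use REML. The engine reproduces R metafor's
`rma.mv` to ~1e−5 on shared problems (cross-checked in the test suite) and
its optimum dominates a brute-force likelihood grid.

Degenerate inputs: a single effect size is fittable only with the residual
component pinned (`fixed_components={"effect_size_id": 0.0}`), returning
the effect itself with SE = √v. Rank-deficient designs raise an error
naming the aliased columns. Ties in AIC go to the structure with fewer
terms.

## Publication bias and sensitivity

The modified Egger test refits the AIC-selected moderator model (candidate
pool: merged trophic level, calcifier, stressor, in isolation and all
combinations, plus intercept-only) with each effect's standard error as an
additional continuous moderator; the SE coefficient's Wald p-value is the
asymmetry test. Funnel tables report effect against precision (1/SE),
optionally residualized against the fitted model so heterogeneity is not
mistaken for asymmetry.

Sensitivity variants re-run the pooled models: (1) r = 0.9 in V; (2) the
metabolism sign flip, implemented as a reciprocal transform (x → 1/x,
delta-method SD) of metabolism group means *before* recomputing effect
sizes — an exact sign flip for individual lnRRs, and the correct
arm-level operation for the pooled main effects, which are not sign-
symmetric under post-hoc negation. The comparison report flags any level
whose CI exclusion-of-zero status changes. Note that under full REML
refitting, raising r does not mathematically guarantee larger pooled SEs
(the residual variance component re-partitions); with variance components
held fixed the r = 0.9 fit is conservative by construction, and that is the
property the test suite verifies.

## Synthetic data

The generator draws a hierarchy (studies → species → experiments →
response observations) with per-study latitudes and countries, trophic
levels per species, and per-arm lognormal data. True individual effects are
θ = true_main(stressor, trophic) + latitude trend + study + species +
observation random effects; expected arm means are CT·e^θ with the combined
arm CT·e^(θ_oa + θ_ow + γ), so the injected γ is exactly the interaction
lnRR, and with γ = 0 the main effect equals θ exactly. Arm summaries are
the sample mean/SD of `group_n` lognormal draws at constant CV, so means
are positive by construction. A truth ledger records every θ, γ, the
orientation decision at the truth, and the implied noise-free label.

Defaults emulate a realistic evidence base at the scale of the marine
OA × OW literature: 54 studies × 3 experiments = 162 factorial experiments
with 3 responses each (≈ 486 observations), arm n = 10, CV = 0.2 (interaction
sampling variance ≈ 0.016), between-study SD 0.10, between-species 0.05,
residual 0.10 on the lnRR scale, and main-effect patterns in which
acidification is hardest on herbivores while predators are the most
tolerant level. What the generator does *not* emulate: unbalanced moderator
distributions, missing arms, reporting errors, response-variable-specific
variance structure, or true publication selection — so passing recovery
tests demonstrates correctness of the estimators under the stated model,
not robustness to those real-data pathologies.

## Problem sizes in the validation suite

Calibration checks run at sizes chosen to balance Monte-Carlo error against
desk-scale runtimes: classifier type-I error on 1000 additive-truth
experiments; ±0.6 interaction recovery on 300 experiments per sign at
v ≈ 0.016; CI coverage over 500 replicates of 100 effects in 25 studies;
Q_M size over 1000 replicates of 90 effects in 30 studies; Egger size over
400 symmetric funnels (k = 100) and power over 150 biased funnels (k = 200,
slope 0.5 on SE ~ U[0.02, 0.5]). The acceptance script runs the full
pipeline on a 36-study × 2-experiment × 2-response synthetic base (144
observations) with random-structure selection enabled.

## Known limitations

* Wald-z inference is mildly liberal at small k (no Knapp–Hartung or
  cluster-robust options).
* No Bayesian fitting, phylogenetic covariance, trim-and-fill or
  selection-model bias corrections (out of scope by design).
* The deposited dataset's exact column layout must be user-mapped via the
  schema config; the package does not guess foreign headers.
* Dense V handling scales as O(k³) per likelihood evaluation; fine to a few
  thousand effect sizes, not beyond.
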