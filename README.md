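# stressmeta

Factorial multiple-stressor meta-analysis for marine climate-change
experiments: log-response-ratio effect sizes, interaction-type
classification, and multilevel random-effects models with known sampling
covariance.

## The problem

Marine organisms face ocean acidification (OA) and ocean warming (OW)
simultaneously, and fully factorial experiments (control CT, OA alone, OW
alone, combined OAW) are the only design that can separate each stressor's
effect from their interaction. Synthesizing many such experiments raises
three coupled statistical problems:

1. **Effect sizes.** For each observation with arm means X̄, SDs S and
   sample sizes N, the package computes log response ratios:
   * individual effects lnRR_oa = ln(X̄_oa / X̄_ct) (likewise OW);
   * main (overall) effects, e.g. for OA
     `lnRR_OA = ln(X̄_OA + X̄_OAW) − ln(X̄_CT + X̄_OW)`,
     the stressor's net effect pooled over presence/absence of the other;
   * the interaction
     `lnRR_OAW = ln(X̄_OAW · X̄_CT) − ln(X̄_OA · X̄_OW)`,
     the combined response minus the additive (log-scale) expectation.
   Sampling variances follow the delta method (per-arm terms S²/(N·X̄²)).
2. **Interaction classification.** The interaction's sign is inverted when
   the additive expectation from the individual effects is negative, so
   that positive always means amplification. The oriented interaction is
   then *synergistic* if its 95% CI lies above zero, *antagonistic* if
   below, *additive* if it spans zero; frequencies are tabulated by trophic
   level, calcifier status and climate region and compared by Pearson
   chi-square.
3. **Pooling.** Effect sizes are clustered (same study, species, shared
   control arms), so pooled estimates come from multilevel random-effects
   models `y ~ N(Xβ, V + Σ_t σ_t² Z_t Z_tᵀ)` where V is the known
   block sampling covariance (within-cluster correlation r = 0.5; r = 0.9
   as a sensitivity) and the σ_t² are study/species/… variance components
   estimated by REML (ML for AIC model comparison). Moderator effects are
   tested with the Wald omnibus Q_M; funnel asymmetry with a modified Egger
   regression (SE as a moderator inside the multilevel model).

A synthetic-data generator produces datasets with this full hierarchical
structure and a ground-truth ledger, so every stage can be validated by
parameter recovery.

## Worked example

```python
from stressmeta import fixture_library, main_lnrr, interaction_lnrr, lnrr_to_percent
from stressmeta import individual_lnrr, orient_interaction, classify_interaction

e = fixture_library()["E2"]          # CT(10,1,10) OA(8,1,10) OW(7,1,10) OAW(3,1,10)
inter = interaction_lnrr(e)
print(round(inter.value, 5), round(inter.variance, 7))
# -0.62415 0.0157144

rec = classify_interaction(orient_interaction(
    individual_lnrr(e.oa, e.ct, es_type="individual_oa", exp=e),
    individual_lnrr(e.ow, e.ct, es_type="individual_ow", exp=e),
    inter,
))
print(rec.inverted, rec.label, round(rec.ci_low, 4), round(rec.ci_high, 4))
# True synergistic 0.3785 0.8698
```

Both individual effects are negative (ln 0.8, ln 0.7), so the additive
expectation is negative and the raw interaction (−0.624) is inverted; the
oriented interaction's CI lies above zero: the combined impact is
synergistically worse than additivity predicts. `lnrr_to_percent(0.206)`
returns `22.9`, the percent change a lnRR corresponds to.

An end-to-end run on synthetic data:

```bash
stressmeta report --out-dir run_out --seed 7
```

writes effect sizes, classifications, frequency tables and chi-squares,
pooled estimates per stressor × trophic level, latitude meta-regressions,
Egger/funnel outputs, sensitivity comparisons (r = 0.9, metabolism sign
flip) and a manifest under `run_out/`.

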