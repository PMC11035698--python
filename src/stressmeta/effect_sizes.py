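"""Log-response-ratio effect sizes for 2x2 factorial stressor experiments.

Three effect sizes are computed per factorial observation:

* *individual* effects — lnRR of a single-stressor arm against the control,
  ln(X_oa / X_ct) and ln(X_ow / X_ct); used for interaction sign
  orientation and classification;
* *main* (overall) effects — lnRR of the pooled arms containing a stressor
  against the pooled arms lacking it, ln((X_oa + X_oaw) / (X_ct + X_ow)),
  which measures a stressor's net effect in the presence and absence of the
  other stressor;
* the *interaction* effect — the observed combined response minus the
  additive (log-scale) expectation, ln(X_oaw * X_ct) - ln(X_oa * X_ow).

Sampling variances follow the delta method: each arm contributes
S^2 / (N * mean^2).  Individual effects are printed without a variance in
the source formulation; the standard Hedges-style lnRR variance (the same
per-arm terms as the interaction variance) is used so they can carry
confidence intervals.  Natural logarithms throughout; no small-sample bias
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .study_data import FactorialExperiment, ObservationKey, TreatmentGroup

__all__ = [
    "EffectSize",
    "individual_lnrr",
    "main_lnrr",
    "interaction_lnrr",
    "lnrr_to_percent",
    "compute_effect_table",
    "EFFECT_TYPES",
]

EFFECT_TYPES = ("individual_oa", "individual_ow", "main_oa", "main_ow", "interaction")


@dataclass(frozen=True)
class EffectSize:
    """A log response ratio with its sampling variance and provenance."""

    value: float
    variance: float
    es_type: str
    key: ObservationKey
    moderators: dict | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"effect size must be finite, got {self.value}")
        if not self.variance > 0:
            raise ValueError(f"sampling variance must be > 0, got {self.variance}")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def _require_positive(*groups: TreatmentGroup) -> None:
    for g in groups:
        if g.mean <= 0:
            raise ValueError(f"group mean must be > 0 for log ratios, got {g.mean}")


def _arm_term(g: TreatmentGroup) -> float:
    """Per-arm delta-method variance contribution S^2 / (N * mean^2)."""
    return g.sd**2 / (g.n * g.mean**2)


def _key(exp: FactorialExperiment | None, es_type: str) -> ObservationKey:
    if exp is None:
        return ObservationKey(cluster_id="adhoc", effect_size_id=f"adhoc:{es_type}")
    return ObservationKey(
        cluster_id=exp.cluster_id,
        effect_size_id=f"{exp.observation_id}:{es_type}",
    )


def individual_lnrr(
    treat: TreatmentGroup,
    ctrl: TreatmentGroup,
    *,
    es_type: str = "individual_oa",
    exp: FactorialExperiment | None = None,
) -> EffectSize:
    """lnRR of a single-stressor arm versus the control arm."""
    _require_positive(treat, ctrl)
    value = math.log(treat.mean) - math.log(ctrl.mean)
    variance = _arm_term(treat) + _arm_term(ctrl)
    return EffectSize(value, variance, es_type, _key(exp, es_type),
                      exp.moderators() if exp is not None else None)


def main_lnrr(exp: FactorialExperiment, stressor: Literal["OA", "OW"]) -> EffectSize:
    """Main (overall) effect of one stressor from the full factorial.

    For OA: ln(X_oa + X_oaw) - ln(X_ct + X_ow); variance
    (X_oa + X_oaw)^-2 (S_oa^2/N_oa + S_oaw^2/N_oaw)
    + (X_ow + X_ct)^-2 (S_ow^2/N_ow + S_ct^2/N_ct).
    The OW effect swaps the roles of the OA and OW arms.
    """
    if stressor not in ("OA", "OW"):
        raise ValueError(f"stressor must be 'OA' or 'OW', got {stressor!r}")
    _require_positive(exp.ct, exp.oa, exp.ow, exp.oaw)
    present = exp.oa if stressor == "OA" else exp.ow
    absent = exp.ow if stressor == "OA" else exp.oa
    num = present.mean + exp.oaw.mean
    den = absent.mean + exp.ct.mean
    value = math.log(num) - math.log(den)
    variance = (1.0 / num) ** 2 * (present.sd**2 / present.n + exp.oaw.sd**2 / exp.oaw.n) + (
        1.0 / den
    ) ** 2 * (absent.sd**2 / absent.n + exp.ct.sd**2 / exp.ct.n)
    es_type = "main_oa" if stressor == "OA" else "main_ow"
    return EffectSize(value, variance, es_type, _key(exp, es_type), exp.moderators())


def interaction_lnrr(exp: FactorialExperiment) -> EffectSize:
    """Interaction effect: combined response versus the additive expectation.

    value = ln(X_oaw * X_ct) - ln(X_oa * X_ow); zero when the combined arm
    equals the multiplicative prediction X_oa * X_ow / X_ct.  The variance
    sums all four per-arm delta-method terms.
    """
    _require_positive(exp.ct, exp.oa, exp.ow, exp.oaw)
    value = (
        math.log(exp.oaw.mean) + math.log(exp.ct.mean)
        - math.log(exp.oa.mean) - math.log(exp.ow.mean)
    )
    variance = sum(_arm_term(g) for g in (exp.oa, exp.ow, exp.oaw, exp.ct))
    return EffectSize(value, variance, "interaction", _key(exp, "interaction"), exp.moderators())


def lnrr_to_percent(value: float) -> float:
    """Percent change implied by a lnRR: 100 * (e^value - 1)."""
    if not math.isfinite(value):
        raise ValueError(f"lnRR must be finite, got {value}")
    return 100.0 * (math.exp(value) - 1.0)


def compute_effect_table(
    experiments: Iterable[FactorialExperiment],
    es_types: Iterable[str] = EFFECT_TYPES,
) -> pd.DataFrame:
    """Long-format effect-size table: one row per (observation, effect type).

    Columns: ``effect_size_id``, ``cluster_id``, ``es_type``, ``value``,
    ``variance``, ``stressor`` (OA/OW/OAxOW), and every moderator carried by
    the experiments.  This is the working currency of the meta-analytic
    modules.
    """
    es_types = tuple(es_types)
    unknown = set(es_types) - set(EFFECT_TYPES)
    if unknown:
        raise ValueError(f"unknown effect types: {sorted(unknown)}")
    rows = []
    for exp in experiments:
        effects: list[EffectSize] = []
        if "individual_oa" in es_types:
            effects.append(individual_lnrr(exp.oa, exp.ct, es_type="individual_oa", exp=exp))
        if "individual_ow" in es_types:
            effects.append(individual_lnrr(exp.ow, exp.ct, es_type="individual_ow", exp=exp))
        if "main_oa" in es_types:
            effects.append(main_lnrr(exp, "OA"))
        if "main_ow" in es_types:
            effects.append(main_lnrr(exp, "OW"))
        if "interaction" in es_types:
            effects.append(interaction_lnrr(exp))
        for es in effects:
            row = {
                "effect_size_id": es.key.effect_size_id,
                "cluster_id": es.key.cluster_id,
                "es_type": es.es_type,
                "value": es.value,
                "variance": es.variance,
                "stressor": {
                    "individual_oa": "OA",
                    "main_oa": "OA",
                    "individual_ow": "OW",
                    "main_ow": "OW",
                    "interaction": "OAxOW",
                }[es.es_type],
            }
            row.update(es.moderators or {})
            rows.append(row)
    return pd.DataFrame(rows)
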