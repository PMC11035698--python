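"""Publication-bias diagnostics and sensitivity re-analyses.

Funnel asymmetry is assessed inside the multilevel model: the modified
Egger test refits the AIC-selected moderator model with each effect size's
standard error appended as a continuous moderator; a non-significant SE
coefficient indicates no detectable small-study asymmetry.  Funnel data
(effect vs precision = 1/SE) can be residualized against the selected
moderators so heterogeneity does not masquerade as asymmetry.

Two sensitivity variants re-run the analysis: a more conservative
within-cluster correlation (r = 0.9 instead of 0.5) in the sampling
variance-covariance matrix, and a metabolism sign flip, in which metabolic
responses are inverted at the group-mean level (higher metabolism read as a
stress cost rather than a benefit) before the main effects are recomputed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .effect_sizes import compute_effect_table
from .multilevel_meta import MetaFit, RandomStructure, VMatrix, build_vmatrix, fit_meta
from .study_data import FactorialExperiment

__all__ = [
    "EggerResult",
    "select_bias_moderators",
    "egger_test",
    "funnel_data",
    "flip_metabolism",
    "sensitivity_rerun",
    "SENSITIVITY_VARIANTS",
]

SENSITIVITY_VARIANTS = ("r09", "metabolism_flip")

#: moderators considered, in isolation and combination, for the bias model
DEFAULT_BIAS_CANDIDATES = ("trophic_level_merged", "calcifier", "stressor")


@dataclass
class EggerResult:
    """Outcome of the modified Egger regression within the multilevel model."""

    se_coefficient: float
    se_coefficient_se: float
    se_coefficient_p: float
    moderators: tuple[str, ...]
    model: MetaFit

    @property
    def asymmetric(self) -> bool:
        return self.se_coefficient_p < 0.05


def select_bias_moderators(
    effects: pd.DataFrame,
    V: VMatrix,
    random: RandomStructure = RandomStructure(),
    candidates: Sequence[str] = DEFAULT_BIAS_CANDIDATES,
    seed: int | None = 0,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """AIC-select the moderator set for the bias model.

    All subsets of ``candidates`` (including the empty, intercept-only
    model) are fitted with ML and compared by AIC.  Returns the winning
    subset and the AIC ladder.
    """
    rows = []
    best: tuple[float, tuple[str, ...]] | None = None
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            fit = fit_meta(effects, V, moderators=list(subset) or None,
                           random=random, method="ML", seed=seed)
            rows.append({"moderators": "+".join(subset) or "(intercept)",
                         "aic": fit.aic, "loglik": fit.loglik})
            key = (fit.aic, subset)
            if best is None or key < best:
                best = key
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    assert best is not None
    return best[1], table


def egger_test(
    effects: pd.DataFrame,
    V: VMatrix,
    random: RandomStructure = RandomStructure(),
    moderators: Sequence[str] | None = None,
    seed: int | None = 0,
) -> EggerResult:
    """Modified Egger regression: SE as a moderator in the multilevel model.

    ``moderators`` defaults to the AIC-selected set from
    :func:`select_bias_moderators`.  Raises if the SE column is degenerate
    or collinear with the moderators.
    """
    if moderators is None:
        moderators, _ = select_bias_moderators(effects, V, random, seed=seed)
    eff = effects.copy()
    eff["standard_error"] = np.sqrt(eff["variance"].to_numpy(dtype=float))
    if np.ptp(eff["standard_error"].to_numpy()) == 0:
        raise ValueError("all effect sizes have identical SE; Egger moderator is degenerate")
    fit = fit_meta(
        eff, V, moderators=list(moderators) + ["standard_error"],
        random=random, method="REML", seed=seed,
    )
    return EggerResult(
        se_coefficient=float(fit.beta["standard_error"]),
        se_coefficient_se=float(fit.se["standard_error"]),
        se_coefficient_p=float(fit.pval["standard_error"]),
        moderators=tuple(moderators),
        model=fit,
    )


def funnel_data(
    effects: pd.DataFrame,
    model: MetaFit | None = None,
) -> pd.DataFrame:
    """Table of (value, se, precision = 1/SE) for funnel plotting.

    When ``model`` is given, ``value`` is residualized against the model's
    fitted means (meta-analytic residual funnel), so moderator-driven
    heterogeneity is removed before asymmetry is judged visually.
    """
    if effects.empty:
        return pd.DataFrame(columns=["effect_size_id", "value", "se", "precision"])
    se = np.sqrt(effects["variance"].to_numpy(dtype=float))
    value = effects["value"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "effect_size_id": effects["effect_size_id"]
            if "effect_size_id" in effects else np.arange(len(effects)),
            "value": value,
            "se": se,
            "precision": 1.0 / se,
        }
    )
    if model is not None:
        out["value"] = value - model.fitted
    return out


def flip_metabolism(experiments: Sequence[FactorialExperiment]) -> list[FactorialExperiment]:
    """Invert metabolism responses at the group-mean level (x -> 1/x).

    Applied *before* effect sizes are recomputed: for individual lnRRs this
    is an exact sign flip, and the main (pooled-arm) effects then aggregate
    the inverted scale.  The reciprocal preserves each arm's coefficient of
    variation, so delta-method sampling variances are unchanged.
    """
    out = []
    for e in experiments:
        if e.response_variable == "metabolism":
            e = dc_replace(
                e,
                ct=e.ct.reciprocal(), oa=e.oa.reciprocal(),
                ow=e.ow.reciprocal(), oaw=e.oaw.reciprocal(),
            )
        out.append(e)
    return out


def _pooled_with_significance(
    experiments: Sequence[FactorialExperiment],
    es_types: Sequence[str],
    grouping: Sequence[str],
    random: RandomStructure,
    r: float,
    seed: int | None,
) -> pd.DataFrame:
    from .multilevel_meta import pooled_by_level  # local to keep import graph simple

    effects = compute_effect_table(experiments, es_types=es_types)
    V = build_vmatrix(effects, r=r)
    table, _ = pooled_by_level(effects, V, random=random, grouping=grouping, seed=seed)
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return table


def sensitivity_rerun(
    experiments: Sequence[FactorialExperiment],
    variant: str,
    *,
    grouping: Sequence[str] = ("stressor", "trophic_level_merged"),
    es_types: Sequence[str] = ("main_oa", "main_ow"),
    random: RandomStructure = RandomStructure(),
    r_primary: float = 0.5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Re-run the pooled models under a sensitivity variant and compare.

    ``variant`` is ``"r09"`` (V matrix with within-cluster correlation 0.9)
    or ``"metabolism_flip"``.  Returns the primary and variant estimates
    side by side with a ``significance_flipped`` flag marking any level
    whose CI exclusion-of-zero status changed.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {SENSITIVITY_VARIANTS}")
    base = _pooled_with_significance(experiments, es_types, grouping, random, r_primary, seed)
    if variant == "r09":
        alt = _pooled_with_significance(experiments, es_types, grouping, random, 0.9, seed)
    else:
        alt = _pooled_with_significance(
            flip_metabolism(experiments), es_types, grouping, random, r_primary, seed
        )
    merged = base.merge(alt, on="level", suffixes=("_primary", f"_{variant}"))
    merged["significance_flipped"] = (
        merged["significant_primary"] != merged[f"significant_{variant}"]
    )
    return merged
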