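"""Sign orientation and classification of factorial interaction effects.

A raw interaction lnRR says whether the combined response exceeded or fell
short of the additive expectation *in the response's own direction*.  To
classify interactions irrespective of direction, the sign is inverted
whenever the additive expectation from the two individual effects is
negative: when both individual effects are negative, or when they oppose
and the negative one dominates in absolute value.  After orientation,
positive = amplification beyond additivity (synergism) and negative =
dampening (antagonism).

"Crossing zero" is operationalized as the 95% Wald interval of the oriented
interaction containing zero; an interval entirely above zero is synergistic,
entirely below antagonistic, and spanning zero additive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import EffectSize
from .study_data import ObservationKey

__all__ = [
    "LABELS",
    "InteractionRecord",
    "FrequencyTable",
    "KeyMismatchError",
    "orient_interaction",
    "classify_interaction",
    "records_from_table",
    "tabulate_frequencies",
    "chi_square_independence",
]

LABELS = ("additive", "antagonistic", "synergistic")


class KeyMismatchError(ValueError):
    """Effect sizes passed together do not belong to the same experiment."""


@dataclass(frozen=True)
class InteractionRecord:
    raw_value: float
    variance: float
    inverted: bool
    oriented_value: float
    key: ObservationKey
    ci_low: float | None = None
    ci_high: float | None = None
    label: str | None = None
    moderators: dict | None = None


def _observation_of(es: EffectSize) -> str:
    return es.key.effect_size_id.rsplit(":", 1)[0]


def orient_interaction(
    ind_oa: EffectSize, ind_ow: EffectSize, inter: EffectSize
) -> InteractionRecord:
    """Apply the sign-inversion convention to a raw interaction effect.

    Inversion is decided solely from the two *individual* effect sizes of
    the same experiment: invert when both are negative, or when they have
    opposite signs and the negative one has the larger absolute value.
    The variance is unchanged by a sign flip.
    """
    obs = {_observation_of(ind_oa), _observation_of(ind_ow), _observation_of(inter)}
    if len(obs) != 1:
        raise KeyMismatchError(
            f"individual and interaction effects come from different observations: {sorted(obs)}"
        )
    a, w = ind_oa.value, ind_ow.value
    inverted = (a < 0 and w < 0) or (a * w < 0 and min(a, w) < 0 and abs(min(a, w)) > abs(max(a, w)))
    oriented = -inter.value if inverted else inter.value
    return InteractionRecord(
        raw_value=inter.value,
        variance=inter.variance,
        inverted=inverted,
        oriented_value=oriented,
        key=inter.key,
        moderators=inter.moderators,
    )


def classify_interaction(record: InteractionRecord, alpha: float = 0.05) -> InteractionRecord:
    """Attach the Wald CI and the additive/antagonistic/synergistic label."""
    if not record.variance > 0:
        raise ValueError(f"variance must be > 0, got {record.variance}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(record.variance)
    lo, hi = record.oriented_value - half, record.oriented_value + half
    if lo > 0:
        label = "synergistic"
    elif hi < 0:
        label = "antagonistic"
    else:
        label = "additive"
    return replace(record, ci_low=lo, ci_high=hi, label=label)


def records_from_table(effects: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Orient and classify every observation of a long effect-size table.

    ``effects`` must contain ``individual_oa``, ``individual_ow`` and
    ``interaction`` rows sharing ``observation_id``.  Returns one row per
    observation with the oriented value, CI, and label, carrying all
    moderator columns through.
    """
    need = {"individual_oa", "individual_ow", "interaction"}
    have = set(effects["es_type"])
    if not need <= have:
        raise ValueError(f"effect table lacks types {sorted(need - have)}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    wide = effects.pivot(index="observation_id", columns="es_type", values="value")
    out = effects.loc[effects["es_type"] == "interaction"].copy()
    out = out.set_index("observation_id")
    ia = wide.loc[out.index, "individual_oa"].to_numpy()
    iw = wide.loc[out.index, "individual_ow"].to_numpy()
    neg_sum = (
        ((ia < 0) & (iw < 0))
        | ((ia * iw < 0) & (np.minimum(ia, iw) < 0)
           & (np.abs(np.minimum(ia, iw)) > np.abs(np.maximum(ia, iw))))
    )
    out["raw_value"] = out["value"]
    out["inverted"] = neg_sum
    out["oriented_value"] = np.where(neg_sum, -out["value"], out["value"])
    half = z * np.sqrt(out["variance"].to_numpy())
    out["ci_low"] = out["oriented_value"] - half
    out["ci_high"] = out["oriented_value"] + half
    out["label"] = np.select(
        [out["ci_low"] > 0, out["ci_high"] < 0], ["synergistic", "antagonistic"], "additive"
    )
    return out.reset_index().drop(columns=["value"])


@dataclass
class FrequencyTable:
    """Counts of interaction labels, optionally split by a moderator."""

    grouping: str | None
    counts: pd.DataFrame  # index: group levels (or 'all'); columns: LABELS
    k_total: int

    @property
    def percentages(self) -> pd.DataFrame:
        """Row percentages rounded to integers, for report parity."""
        pct = self.counts.div(self.counts.sum(axis=1), axis=0) * 100.0
        return pct.round(0).astype(int)


def tabulate_frequencies(
    records: pd.DataFrame | Sequence[InteractionRecord],
    grouping: str | None = None,
) -> FrequencyTable:
    """Tabulate label frequencies overall or by one moderator column."""
    if not isinstance(records, pd.DataFrame):
        rows = []
        for r in records:
            if r.label is None:
                raise ValueError("records must be classified before tabulation")
            row = {"effect_size_id": r.key.effect_size_id, "label": r.label}
            row.update(r.moderators or {})
            rows.append(row)
        records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("cannot tabulate an empty record collection")
    if records["effect_size_id"].duplicated().any():
        dup = records.loc[records["effect_size_id"].duplicated(), "effect_size_id"]
        raise ValueError(f"duplicate record keys: {sorted(set(dup))}")
    key = records[grouping] if grouping else pd.Series("all", index=records.index)
    counts = (
        pd.crosstab(key, records["label"])
        .reindex(columns=LABELS, fill_value=0)
    )
    counts.index.name = grouping or "group"
    return FrequencyTable(grouping=grouping, counts=counts, k_total=int(len(records)))


def chi_square_independence(table: FrequencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of label x group independence (no continuity
    correction); emits a warning when any expected count is below 5."""
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table for an independence test")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero marginal total in frequency table")
    res = stats.chi2_contingency(counts, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            "some expected counts are below 5; the chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)
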