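"""Synthetic factorial-experiment datasets with known ground truth.

The generator emulates the structure the analysis assumes: a hierarchy of
studies, species, and factorial experiments, each experiment contributing
one or more response observations that share a control arm (hence
correlated sampling errors); stressor effects that differ by trophic level
and may trend with absolute latitude; and between-study / between-species /
residual heterogeneity in the true effects.

Arm-level data are lognormal, so all group means are positive by
construction and the log response ratio is the natural effect scale; the
coefficient of variation is constant across arms.  Expected arm means obey

    CT = baseline,  OA = CT e^{theta_oa},  OW = CT e^{theta_ow},
    OAW = CT e^{theta_oa + theta_ow + gamma},

so ``gamma`` is exactly the injected interaction lnRR (zero for additive
truth).  Every draw's true parameters are recorded in a truth ledger, so
downstream stages can be scored without re-deriving ground truth.

Default sizes mirror a realistic multiple-stressor evidence base: 54
studies x 3 experiments = 162 factorial experiments with 3 response
observations each (~486 effect-size rows per effect type), arm n = 10,
CV = 0.2 — which puts the interaction sampling variance near 0.016, typical
of organismal response data at that replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .study_data import (
    RESPONSE_VARIABLES,
    TROPHIC_LEVELS,
    FactorialExperiment,
    TreatmentGroup,
)

__all__ = ["SimulationConfig", "simulate_dataset", "fixture_library"]

#: default true main effects (lnRR) per stressor x trophic level; the
#: qualitative pattern — acidification hardest on herbivores, warming mildly
#: beneficial to producers and predators, predators most tolerant overall —
#: mirrors what marine multiple-stressor syntheses typically find.
DEFAULT_TRUE_MAIN: dict[tuple[str, str], float] = {
    ("OA", "primary_producer"): 0.05,
    ("OA", "herbivore"): -0.25,
    ("OA", "meso_predator"): -0.10,
    ("OA", "top_predator"): 0.00,
    ("OW", "primary_producer"): 0.10,
    ("OW", "herbivore"): -0.20,
    ("OW", "meso_predator"): 0.05,
    ("OW", "top_predator"): 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic evidence base.

    Heterogeneity SDs (``sigma_*``) act on the lnRR scale; ``cv`` is the
    within-arm coefficient of variation of the raw response;
    ``true_interaction`` is the injected interaction lnRR (scalar applied
    to every experiment, or a per-trophic-level map); ``latitude_slope``
    maps trophic level to a lnRR change per degree of absolute latitude
    (default zero everywhere).
    """

    n_studies: int = 54
    species_per_study: int = 1
    experiments_per_species: int = 3
    responses_per_experiment: int = 3
    group_n: int = 10
    cv: float = 0.2
    baseline_mean: float = 10.0
    true_main: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_MAIN)
    )
    true_interaction: float | Mapping[str, float] = 0.0
    sigma_study: float = 0.10
    sigma_species: float = 0.05
    sigma_residual: float = 0.10
    latitude_slope: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TROPHIC_LEVELS}
    )
    calcifier_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_n < 2:
            raise ValueError("group_n must be >= 2")
        if not self.cv > 0:
            raise ValueError("cv must be > 0")
        if not self.baseline_mean > 0:
            raise ValueError("baseline_mean must be > 0")
        for name in ("sigma_study", "sigma_species", "sigma_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_studies", "species_per_study",
                     "experiments_per_species", "responses_per_experiment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


_COUNTRIES = (
    "australia", "chile", "china", "france", "japan",
    "norway", "south_africa", "spain", "sweden", "usa",
)


def _lognormal_arm(rng: np.random.Generator, mean: float, cv: float, n: int) -> TreatmentGroup:
    """Summarize ``n`` lognormal draws with the given expectation and CV."""
    s2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - s2 / 2.0
    x = rng.lognormal(mu, math.sqrt(s2), size=n)
    return TreatmentGroup(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=n)


def _interaction_for(cfg: SimulationConfig, trophic: str) -> float:
    if isinstance(cfg.true_interaction, Mapping):
        return float(cfg.true_interaction.get(trophic, 0.0))
    return float(cfg.true_interaction)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FactorialExperiment], pd.DataFrame]:
    """Draw a dataset and its truth ledger.

    Returns the experiments and a DataFrame with one row per observation
    recording every injected parameter: the true individual lnRRs
    (``theta_oa``, ``theta_ow``, heterogeneity included), the injected
    interaction ``gamma``, whether the orientation rule flips its sign at
    the truth, and the implied noise-free label (``additive`` when gamma is
    exactly 0, otherwise the oriented sign).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    experiments: list[FactorialExperiment] = []
    truth_rows: list[dict] = []
    obs_counter = 0
    for si in range(config.n_studies):
        study_id = f"S{si:03d}"
        country = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]
        author_group = f"A{int(rng.integers(max(config.n_studies // 2, 1))):03d}"
        latitude = float(rng.uniform(-70.0, 70.0))
        u_study = rng.normal(0.0, config.sigma_study, size=2)
        for pi in range(config.species_per_study):
            species_id = f"S{si:03d}_sp{pi}"
            trophic = TROPHIC_LEVELS[int(rng.integers(len(TROPHIC_LEVELS)))]
            calcifier = bool(rng.random() < config.calcifier_prob)
            u_species = rng.normal(0.0, config.sigma_species, size=2)
            for ei in range(config.experiments_per_species):
                experiment_id = f"{species_id}_e{ei}"
                gamma = _interaction_for(config, trophic)
                for ri in range(config.responses_per_experiment):
                    response = RESPONSE_VARIABLES[int(rng.integers(len(RESPONSE_VARIABLES)))]
                    e_obs = rng.normal(0.0, config.sigma_residual, size=2)
                    lat_shift = config.latitude_slope.get(trophic, 0.0) * abs(latitude)
                    theta_oa = (
                        config.true_main[("OA", trophic)] + lat_shift
                        + u_study[0] + u_species[0] + e_obs[0]
                    )
                    theta_ow = (
                        config.true_main[("OW", trophic)] + lat_shift
                        + u_study[1] + u_species[1] + e_obs[1]
                    )
                    m_ct = config.baseline_mean
                    exp = FactorialExperiment(
                        observation_id=f"obs{obs_counter:05d}",
                        experiment_id=experiment_id,
                        study_id=study_id,
                        species_id=species_id,
                        author_group=author_group,
                        country=country,
                        trophic_level=trophic,
                        calcifier=calcifier,
                        response_variable=response,
                        latitude=latitude,
                        ct=_lognormal_arm(rng, m_ct, config.cv, config.group_n),
                        oa=_lognormal_arm(rng, m_ct * math.exp(theta_oa), config.cv, config.group_n),
                        ow=_lognormal_arm(rng, m_ct * math.exp(theta_ow), config.cv, config.group_n),
                        oaw=_lognormal_arm(
                            rng, m_ct * math.exp(theta_oa + theta_ow + gamma),
                            config.cv, config.group_n,
                        ),
                    )
                    # orientation at the truth: additive expectation negative?
                    inverted = (theta_oa < 0 and theta_ow < 0) or (
                        theta_oa * theta_ow < 0
                        and abs(min(theta_oa, theta_ow)) > abs(max(theta_oa, theta_ow))
                    )
                    oriented_gamma = -gamma if inverted else gamma
                    label = (
                        "additive" if gamma == 0.0
                        else "synergistic" if oriented_gamma > 0 else "antagonistic"
                    )
                    truth_rows.append(
                        {
                            "observation_id": exp.observation_id,
                            "experiment_id": experiment_id,
                            "study_id": study_id,
                            "species_id": species_id,
                            "trophic_level": trophic,
                            "response_variable": response,
                            "latitude": latitude,
                            "theta_oa": theta_oa,
                            "theta_ow": theta_ow,
                            "gamma": gamma,
                            "true_inverted": inverted,
                            "true_label": label,
                        }
                    )
                    experiments.append(exp)
                    obs_counter += 1
    return experiments, pd.DataFrame(truth_rows)


def _fixture(
    name: str, means: tuple[float, float, float, float], sd: float, n: int
) -> FactorialExperiment:
    ct, oa, ow, oaw = means
    return FactorialExperiment(
        observation_id=name,
        experiment_id=f"{name}_exp",
        study_id=f"{name}_study",
        species_id=f"{name}_species",
        author_group="fixture_authors",
        country="sweden",
        trophic_level="herbivore",
        calcifier=True,
        response_variable="growth",
        latitude=45.0,
        ct=TreatmentGroup(ct, sd, n),
        oa=TreatmentGroup(oa, sd, n),
        ow=TreatmentGroup(ow, sd, n),
        oaw=TreatmentGroup(oaw, sd, n),
    )


def fixture_library() -> dict[str, FactorialExperiment]:
    """Small hand-checkable factorial experiments used across the test suite.

    * ``E1`` — CT(10,2,10), OA(8,2,10), OW(12,2,10), OAW(9,2,10): opposing
      individual effects, weak (additive) interaction.
    * ``E2`` — CT(10,1,10), OA(8,1,10), OW(7,1,10), OAW(3,1,10): both
      individual effects negative, strong interaction.
    * ``additive_exact`` — OAW = OA * OW / CT, so the interaction lnRR is
      exactly zero.
    * ``null_effect`` — all arms identical; every lnRR is zero.
    """
    lib = {
        "E1": _fixture("E1", (10.0, 8.0, 12.0, 9.0), 2.0, 10),
        "E2": _fixture("E2", (10.0, 8.0, 7.0, 3.0), 1.0, 10),
        "additive_exact": _fixture(
            "additive_exact", (10.0, 8.0, 12.0, 8.0 * 12.0 / 10.0), 2.0, 10
        ),
        "null_effect": _fixture("null_effect", (10.0, 10.0, 10.0, 10.0), 2.0, 10),
    }
    return lib
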