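"""End-to-end orchestration: ingest -> effect sizes -> classification ->
multilevel models -> bias and sensitivity -> report files.

Every stage persists its output as CSV/JSON under the run's output
directory, so any stage can be re-run in isolation, and a manifest records
the configuration hash for exact reproduction.  All randomness flows
through one seeded generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_sensitivity import (
    egger_test,
    funnel_data,
    select_bias_moderators,
    sensitivity_rerun,
)
from .effect_sizes import compute_effect_table
from .interaction_rules import (
    chi_square_independence,
    records_from_table,
    tabulate_frequencies,
)
from .multilevel_meta import (
    RandomStructure,
    build_vmatrix,
    fit_meta,
    latitude_metaregression,
    pooled_by_level,
    select_random_structure,
)
from .study_data import FactorialExperiment, read_experiments
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger("stressmeta")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_RANDOM_CANDIDATES"]

#: candidate random structures compared by ML AIC (effect-size identifier
#: implicit in all of them)
DEFAULT_RANDOM_CANDIDATES = (
    RandomStructure(()),
    RandomStructure(("study_id",)),
    RandomStructure(("species_id",)),
    RandomStructure(("study_id", "species_id")),
    RandomStructure(("study_id", "country")),
    RandomStructure(("study_id", "author_group")),
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the context."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    schema: Mapping[str, str] | None = None
    dispersion_kind: str = "sd"
    simulation: SimulationConfig | None = None
    r: float = 0.5
    alpha: float = 0.05
    select_random: bool = False
    random_terms: tuple[str, ...] = ("study_id",)
    groupings: tuple[str, ...] = (
        "trophic_level",
        "trophic_level_merged",
        "calcifier",
        "climate_region",
    )
    latitude_regression: bool = True
    sensitivity: tuple[str, ...] = ("r09", "metabolism_flip")
    out_dir: str = "stressmeta_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must be in [0, 1), got {self.r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.input_path is None and self.simulation is None:
            raise ValueError("either input_path or a simulation config is required")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        if d.get("simulation") is not None:
            d["simulation"] = {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in d["simulation"].items()
            }
            d["simulation"] = {
                k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in d["simulation"].items()
            }
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(config: RunConfig, out: Path) -> list[FactorialExperiment]:
    if config.input_path is not None:
        experiments, rejects = read_experiments(
            config.input_path, config.schema, dispersion_kind=config.dispersion_kind
        )
        rejects.to_csv(out / "rejected_rows.csv", index=False)
        if len(rejects):
            logger.warning("excluded %d invalid rows (see rejected_rows.csv)", len(rejects))
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        experiments, truth = simulate_dataset(sim)
        truth.to_csv(out / "truth_ledger.csv", index=False)
    if not experiments:
        raise PipelineError("stage 'ingest' produced no valid experiments")
    return experiments


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results and
    writes all report files under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    experiments = _ingest(config, out)
    results["n_experiments"] = len({e.cluster_id for e in experiments})
    results["n_observations"] = len(experiments)

    # --- effect sizes ---------------------------------------------------
    try:
        effects = compute_effect_table(experiments)
    except Exception as exc:
        raise PipelineError(f"stage 'effect_sizes' failed: {exc}") from exc
    effects.to_csv(out / "effect_sizes.csv", index=False)
    results["effects"] = effects

    # --- interaction classification -------------------------------------
    try:
        classified = records_from_table(effects, alpha=config.alpha)
    except Exception as exc:
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc
    classified.to_csv(out / "classification.csv", index=False)
    results["classification"] = classified

    freq_tables: dict[str, dict] = {}
    chisq: dict[str, dict] = {}
    for grouping in (None,) + tuple(config.groupings):
        name = grouping or "overall"
        try:
            ft = tabulate_frequencies(classified, grouping)
        except ValueError as exc:
            raise PipelineError(f"stage 'tabulate:{name}' failed: {exc}") from exc
        ft.counts.to_csv(out / f"frequencies_{name}.csv")
        freq_tables[name] = {
            "counts": ft.counts.to_dict(),
            "percent": ft.percentages.to_dict(),
            "k_total": ft.k_total,
        }
        if grouping is not None and ft.counts.shape[0] >= 2:
            try:
                stat, df, p = chi_square_independence(ft)
                chisq[name] = {"statistic": stat, "df": df, "p": p, "n": ft.k_total}
            except ValueError as exc:
                chisq[name] = {"error": str(exc)}
    (out / "frequencies.json").write_text(json.dumps(freq_tables, indent=2, default=str))
    (out / "chi_square.json").write_text(json.dumps(chisq, indent=2))
    results["frequencies"] = freq_tables
    results["chi_square"] = chisq

    # --- multilevel models ----------------------------------------------
    main_effects = effects.loc[effects["es_type"].isin(["main_oa", "main_ow"])].reset_index(
        drop=True
    )
    V_main = build_vmatrix(main_effects, r=config.r)
    random = RandomStructure(tuple(config.random_terms))
    if config.select_random:
        try:
            random, aic_table = select_random_structure(
                main_effects, V_main, DEFAULT_RANDOM_CANDIDATES
            )
            aic_table.to_csv(out / "random_structure_aic.csv", index=False)
            results["random_structure_aic"] = aic_table
        except Exception as exc:
            raise PipelineError(f"stage 'select_random' failed: {exc}") from exc
    results["random_structure"] = random

    pooled: dict[str, pd.DataFrame] = {}
    for grouping_col in ("stressor",) + tuple(config.groupings):
        cols = ["stressor"] if grouping_col == "stressor" else ["stressor", grouping_col]
        try:
            table, fit = pooled_by_level(
                main_effects, V_main, random=random, grouping=cols, seed=config.seed
            )
        except Exception as exc:
            raise PipelineError(f"stage 'pooled:{grouping_col}' failed: {exc}") from exc
        table.to_csv(out / f"pooled_{grouping_col}.csv", index=False)
        pooled[grouping_col] = table
        results.setdefault("qm", {})[grouping_col] = {
            "qm": fit.qm, "df": fit.qm_df, "p": fit.qm_p,
        }
    # pooled interaction effects (oriented) overall and per grouping
    inter = effects.loc[effects["es_type"] == "interaction"].reset_index(drop=True)
    oriented = inter.copy()
    orient_map = classified.set_index("effect_size_id")["oriented_value"]
    oriented["value"] = oriented["effect_size_id"].map(orient_map)
    V_int = build_vmatrix(oriented, r=config.r)
    try:
        table, _ = pooled_by_level(
            oriented, V_int, random=random, grouping=["trophic_level_merged"], seed=config.seed
        )
    except Exception as exc:
        raise PipelineError(f"stage 'pooled:interaction' failed: {exc}") from exc
    table.to_csv(out / "pooled_interaction.csv", index=False)
    pooled["interaction"] = table
    results["pooled"] = pooled

    # --- latitude meta-regression ----------------------------------------
    if config.latitude_regression:
        lat_rows = []
        for stressor, sub in main_effects.groupby("stressor"):
            sub = sub.reset_index(drop=True)
            try:
                fit = latitude_metaregression(
                    sub, build_vmatrix(sub, r=config.r), random=random, seed=config.seed
                )
                lat_rows.append(
                    {
                        "stressor": stressor,
                        "intercept": fit.beta["intercept"],
                        "slope": fit.beta["abs_latitude"],
                        "slope_se": fit.se["abs_latitude"],
                        "slope_ci_low": fit.ci_low["abs_latitude"],
                        "slope_ci_high": fit.ci_high["abs_latitude"],
                        "slope_p": fit.pval["abs_latitude"],
                        "k": fit.k,
                    }
                )
            except ValueError as exc:
                lat_rows.append({"stressor": stressor, "error": str(exc)})
        lat_table = pd.DataFrame(lat_rows)
        lat_table.to_csv(out / "latitude_regression.csv", index=False)
        results["latitude"] = lat_table

    # --- publication bias -------------------------------------------------
    try:
        bias_mods, bias_aic = select_bias_moderators(
            main_effects, V_main, random=random, seed=config.seed
        )
        bias_aic.to_csv(out / "bias_moderator_aic.csv", index=False)
        egger = egger_test(
            main_effects, V_main, random=random, moderators=bias_mods, seed=config.seed
        )
        (out / "egger.json").write_text(
            json.dumps(
                {
                    "se_coefficient": egger.se_coefficient,
                    "se_coefficient_se": egger.se_coefficient_se,
                    "p": egger.se_coefficient_p,
                    "moderators": list(egger.moderators),
                },
                indent=2,
            )
        )
        funnel = funnel_data(main_effects, model=egger.model)
        funnel.to_csv(out / "funnel.csv", index=False)
        results["egger"] = egger
        results["funnel"] = funnel
    except Exception as exc:
        raise PipelineError(f"stage 'bias' failed: {exc}") from exc

    # --- sensitivity -----------------------------------------------------
    sens: dict[str, pd.DataFrame] = {}
    for variant in config.sensitivity:
        try:
            cmp = sensitivity_rerun(
                experiments, variant, random=random, r_primary=config.r, seed=config.seed
            )
        except Exception as exc:
            raise PipelineError(f"stage 'sensitivity:{variant}' failed: {exc}") from exc
        cmp.to_csv(out / f"sensitivity_{variant}.csv", index=False)
        sens[variant] = cmp
    results["sensitivity"] = sens

    manifest = {
        "package": "stressmeta",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "r": config.r,
        "alpha": config.alpha,
        "random_structure": str(random),
        "n_observations": results["n_observations"],
        "n_experiments": results["n_experiments"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; a ``simulation`` mapping becomes a
    :class:`SimulationConfig` (its ``true_main`` keys given as
    ``"OA:herbivore"`` strings)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        tm = sim.pop("true_main", None)
        if tm is not None:
            sim["true_main"] = {tuple(k.split(":")): float(v) for k, v in tm.items()}
        sim = SimulationConfig(**sim)
    for tup_field in ("random_terms", "groupings", "sensitivity"):
        if tup_field in raw and raw[tup_field] is not None:
            raw[tup_field] = tuple(raw[tup_field])
    return RunConfig(simulation=sim, **raw)
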