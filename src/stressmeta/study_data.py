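"""Ingestion, validation, and harmonization of fully factorial experiment tables.

The atomic record is a :class:`FactorialExperiment`: one organism-level
observation of one response variable under a 2x2 design crossing ocean
acidification (OA) and ocean warming (OW) against a shared control (CT),
with the combined arm (OAW).  Each arm carries the summary statistics
(mean, SD, n) needed for log-response-ratio effect sizes, and the record
carries the moderators used downstream (trophic level, calcifier status,
response variable, latitude, clustering keys).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TROPHIC_LEVELS",
    "MERGED_TROPHIC_LEVELS",
    "RESPONSE_VARIABLES",
    "CLIMATE_REGIONS",
    "DISPERSION_KINDS",
    "TreatmentGroup",
    "FactorialExperiment",
    "ObservationKey",
    "SchemaError",
    "ValidationError",
    "DEFAULT_SCHEMA",
    "harmonize_dispersion",
    "mortality_to_survival",
    "merge_predators",
    "assign_climate_region",
    "read_experiments",
    "write_experiments",
    "experiments_to_frame",
]

TROPHIC_LEVELS = ("primary_producer", "herbivore", "meso_predator", "top_predator")
MERGED_TROPHIC_LEVELS = ("primary_producer", "herbivore", "predator")
RESPONSE_VARIABLES = (
    "calcification",
    "development",
    "growth",
    "metabolism",
    "reproduction",
    "survival",
)
CLIMATE_REGIONS = ("tropical", "subtropical", "temperate")
DISPERSION_KINDS = ("sd", "se", "ci95")

#: conventional z for a 95% interval, used to back-convert CI half-widths
_Z95 = 1.96


class SchemaError(ValueError):
    """A required column is missing from the input table or schema mapping."""


class ValidationError(ValueError):
    """Input values cannot be mapped onto the controlled vocabularies."""


@dataclass(frozen=True)
class TreatmentGroup:
    """Summary statistics of one experimental arm.

    mean must be strictly positive once harmonized (log ratios are taken of
    it), sd is on the same scale as the mean, and n >= 2 replicates are
    required for a meaningful sampling variance.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError(f"group mean must be finite, got {self.mean}")
        if not (self.sd >= 0.0):
            raise ValidationError(f"group sd must be >= 0, got {self.sd}")
        if int(self.n) != self.n or self.n < 2:
            raise ValidationError(f"group n must be an integer >= 2, got {self.n}")

    def scaled(self, c: float) -> "TreatmentGroup":
        """Return a copy with mean and sd multiplied by ``c`` (> 0)."""
        return TreatmentGroup(self.mean * c, self.sd * c, self.n)

    def reciprocal(self) -> "TreatmentGroup":
        """Arm on the inverted response scale (x -> 1/x).

        Delta-method SD: sd(1/X) ~= sd(X) / mean(X)^2, which preserves the
        coefficient of variation.  Used for the metabolism sign-flip
        sensitivity variant, where a higher metabolic rate is re-read as a
        detriment rather than a benefit.
        """
        if self.mean <= 0:
            raise ValidationError("cannot invert a non-positive mean")
        return TreatmentGroup(1.0 / self.mean, self.sd / self.mean**2, self.n)


@dataclass(frozen=True)
class ObservationKey:
    """Keys tying an effect size back to its organism and its own identity.

    ``cluster_id`` groups effect sizes that share sampling errors (same
    organisms, hence same control arm): study x species x experiment.
    ``effect_size_id`` is unique per computed effect size.
    """

    cluster_id: str
    effect_size_id: str


@dataclass
class FactorialExperiment:
    """One response measured on one organism group in a 2x2 factorial design."""

    observation_id: str
    experiment_id: str
    study_id: str
    species_id: str
    author_group: str
    country: str
    trophic_level: str
    calcifier: bool
    response_variable: str
    latitude: float
    ct: TreatmentGroup
    oa: TreatmentGroup
    ow: TreatmentGroup
    oaw: TreatmentGroup

    def __post_init__(self) -> None:
        if self.trophic_level not in TROPHIC_LEVELS:
            raise ValidationError(
                f"unknown trophic level {self.trophic_level!r}; "
                f"expected one of {TROPHIC_LEVELS}"
            )
        if self.response_variable not in RESPONSE_VARIABLES:
            raise ValidationError(
                f"unknown response variable {self.response_variable!r}; "
                f"expected one of {RESPONSE_VARIABLES}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        for arm_name in ("ct", "oa", "ow", "oaw"):
            arm = getattr(self, arm_name)
            if arm.mean <= 0:
                raise ValidationError(
                    f"arm {arm_name} has non-positive mean {arm.mean}; "
                    "log response ratios are undefined"
                )

    @property
    def cluster_id(self) -> str:
        return f"{self.study_id}|{self.species_id}|{self.experiment_id}"

    @property
    def trophic_level_merged(self) -> str:
        return merge_predators(self.trophic_level)

    @property
    def climate_region(self) -> str:
        return assign_climate_region(self.latitude)

    def arms(self) -> dict[str, TreatmentGroup]:
        return {"ct": self.ct, "oa": self.oa, "ow": self.ow, "oaw": self.oaw}

    def moderators(self) -> dict[str, object]:
        """Metadata propagated onto every effect size computed from this record."""
        return {
            "observation_id": self.observation_id,
            "experiment_id": self.experiment_id,
            "study_id": self.study_id,
            "species_id": self.species_id,
            "author_group": self.author_group,
            "country": self.country,
            "trophic_level": self.trophic_level,
            "trophic_level_merged": self.trophic_level_merged,
            "calcifier": self.calcifier,
            "response_variable": self.response_variable,
            "latitude": self.latitude,
            "abs_latitude": abs(self.latitude),
            "climate_region": self.climate_region,
        }


def harmonize_dispersion(value: float, kind: str, n: int) -> float:
    """Convert a reported dispersion to a standard deviation.

    ``kind`` is ``sd`` (returned unchanged), ``se`` (sd = se * sqrt(n)), or
    ``ci95`` (the symmetric half-width of a 95% interval; sd =
    half_width / z * sqrt(n) with z = 1.96).  Asymmetric intervals are not
    representable and must be rejected upstream.
    """
    if kind not in DISPERSION_KINDS:
        raise ValidationError(f"unknown dispersion kind {kind!r}")
    if value < 0:
        raise ValidationError(f"dispersion must be >= 0, got {value}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if kind == "sd":
        return float(value)
    if kind == "se":
        return float(value) * math.sqrt(n)
    return float(value) / _Z95 * math.sqrt(n)


def mortality_to_survival(mortality: float) -> float:
    """Recode a mortality proportion as survival (1 - mortality); SD unchanged."""
    if not 0.0 <= mortality <= 1.0:
        raise ValidationError(f"mortality must be in [0, 1], got {mortality}")
    return 1.0 - mortality


def merge_predators(trophic_level: str) -> str:
    """Collapse meso- and top-predators into a single 'predator' level."""
    if trophic_level in ("meso_predator", "top_predator"):
        return "predator"
    if trophic_level in TROPHIC_LEVELS:
        return trophic_level
    raise ValidationError(f"unknown trophic level {trophic_level!r}")


def assign_climate_region(latitude: float) -> str:
    """Assign a climate region from a signed latitude in degrees.

    Tropical |lat| <= 23.5, subtropical 23.5 < |lat| <= 35, temperate
    |lat| > 35; too few polar observations exist for a separate level, so
    |lat| > 66.5 is folded into temperate.  Boundary latitudes go to the
    equatorward region.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValidationError(f"latitude out of range: {latitude}")
    a = abs(latitude)
    if a <= 23.5:
        return "tropical"
    if a <= 35.0:
        return "subtropical"
    return "temperate"


# Canonical column names; a schema maps these onto the file's own headers.
_META_COLUMNS = (
    "observation_id",
    "experiment_id",
    "study_id",
    "species_id",
    "author_group",
    "country",
    "trophic_level",
    "calcifier",
    "response_variable",
    "latitude",
)
_ARM_COLUMNS = tuple(
    f"{arm}_{stat}" for arm in ("ct", "oa", "ow", "oaw") for stat in ("mean", "disp", "n")
)
DEFAULT_SCHEMA: dict[str, str] = {name: name for name in _META_COLUMNS + _ARM_COLUMNS}
DEFAULT_SCHEMA["dispersion_kind"] = "dispersion_kind"

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _to_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {x!r} as a boolean calcifier flag")


def _row_to_experiment(row: pd.Series, dispersion_kind: str) -> FactorialExperiment:
    arms = {}
    for arm in ("ct", "oa", "ow", "oaw"):
        n = int(row[f"{arm}_n"])
        mean = float(row[f"{arm}_mean"])
        sd = harmonize_dispersion(float(row[f"{arm}_disp"]), dispersion_kind, max(n, 2))
        arms[arm] = TreatmentGroup(mean=mean, sd=sd, n=n)
    return FactorialExperiment(
        observation_id=str(row["observation_id"]),
        experiment_id=str(row["experiment_id"]),
        study_id=str(row["study_id"]),
        species_id=str(row["species_id"]),
        author_group=str(row["author_group"]),
        country=str(row["country"]),
        trophic_level=str(row["trophic_level"]),
        calcifier=_to_bool(row["calcifier"]),
        response_variable=str(row["response_variable"]),
        latitude=float(row["latitude"]),
        **arms,
    )


def read_experiments(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    dispersion_kind: str = "sd",
    sep: str | None = None,
) -> tuple[list[FactorialExperiment], pd.DataFrame]:
    """Read a factorial-experiment table; validate and harmonize each row.

    ``schema`` maps canonical column names (see :data:`DEFAULT_SCHEMA`) to
    the file's headers.  Dispersion is taken per-row from a
    ``dispersion_kind`` column when mapped, otherwise the ``dispersion_kind``
    argument applies to the whole file.  Returns the valid records and a
    report DataFrame of rejected rows (``row`` is the 0-based data row
    number, ``reason`` the violated invariant).  Unknown trophic-level or
    response labels are a hard :class:`ValidationError` (a vocabulary
    problem, not a row-level data problem); structural invariant violations
    (n < 2, non-positive means, bad latitude) are excluded and reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)

    raw = pd.read_csv(path, sep=sep)
    required = list(_META_COLUMNS + _ARM_COLUMNS)
    missing = [schema.get(c, c) for c in required if schema.get(c, c) not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns in {path.name}: {missing}")

    rename = {schema.get(c, c): c for c in required}
    kind_col = schema.get("dispersion_kind")
    per_row_kind = kind_col is not None and kind_col in raw.columns
    if per_row_kind:
        rename[kind_col] = "dispersion_kind"
    df = raw.rename(columns=rename)

    # Vocabulary check up front so the error lists every offending value.
    bad_trophic = sorted(set(df["trophic_level"].astype(str)) - set(TROPHIC_LEVELS))
    bad_response = sorted(set(df["response_variable"].astype(str)) - set(RESPONSE_VARIABLES))
    if bad_trophic or bad_response:
        raise ValidationError(
            f"unmapped labels: trophic_level={bad_trophic}, "
            f"response_variable={bad_response}"
        )

    experiments: list[FactorialExperiment] = []
    rejects: list[dict[str, object]] = []
    for i, row in df.iterrows():
        kind = str(row["dispersion_kind"]) if per_row_kind else dispersion_kind
        try:
            # n >= 2 checked before harmonization so the reason is specific
            for arm in ("ct", "oa", "ow", "oaw"):
                if int(row[f"{arm}_n"]) < 2:
                    raise ValidationError(f"arm {arm} has n < 2")
            experiments.append(_row_to_experiment(row, kind))
        except (ValidationError, ValueError) as exc:
            rejects.append(
                {"row": int(i), "observation_id": row.get("observation_id"), "reason": str(exc)}
            )
    report = pd.DataFrame(rejects, columns=["row", "observation_id", "reason"])
    dup = pd.Series([e.observation_id for e in experiments])
    if dup.duplicated().any():
        raise ValidationError(
            f"duplicate observation_id values: {sorted(dup[dup.duplicated()])}"
        )
    return experiments, report


def experiments_to_frame(experiments: Iterable[FactorialExperiment]) -> pd.DataFrame:
    """Flatten experiments to the canonical wide CSV schema (SD dispersion)."""
    rows = []
    for e in experiments:
        row: dict[str, object] = {c: getattr(e, c) for c in _META_COLUMNS}
        for arm_name, arm in e.arms().items():
            row[f"{arm_name}_mean"] = arm.mean
            row[f"{arm_name}_disp"] = arm.sd
            row[f"{arm_name}_n"] = arm.n
        row["dispersion_kind"] = "sd"
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS + _ARM_COLUMNS) + ["dispersion_kind"])


def write_experiments(experiments: Sequence[FactorialExperiment], path: str | Path) -> Path:
    """Write experiments as CSV in the same schema :func:`read_experiments` accepts."""
    path = Path(path)
    experiments_to_frame(experiments).to_csv(path, index=False)
    return path
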