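"""Domain types, validation and CSV input/output for rangeland transect surveys.

The survey protocol records, at 1-m intervals along a 50-m transect, whether a
thin rod lowered to the ground strikes a grass tuft (its longest and shortest
basal axes are then measured), lands on bare ground within 40 cm of a tuft
(the distance and the nearest species are recorded), or lands in a bare patch
wider than 40 cm (recorded as bare ground only).  Grasses carry an ecological
status (decreaser / increaser I-III, by their response to grazing pressure)
and a forage factor, a 0-10 index of forage production potential.

File formats
------------
survey CSV : site_id, location, position_m, outcome, species_name,
             distance_to_tuft_cm, longest_axis_cm, shortest_axis_cm
traits CSV : species_name, growth_form, ecological_status, forage_factor
PCQ CSV    : site_id, location, point_index, quarter, distance_m, height_m

All files are comma-separated UTF-8 with a header row and "." decimals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthForm",
    "EcologicalStatus",
    "Location",
    "Outcome",
    "SpeciesTrait",
    "PointObservation",
    "SiteSurvey",
    "PCQRecord",
    "AbundanceMatrix",
    "SurveyValidationError",
    "read_traits",
    "write_traits",
    "read_survey",
    "write_survey",
    "read_pcq",
    "write_pcq",
    "to_abundance_matrix",
]


class SurveyValidationError(ValueError):
    """Raised when a survey, trait or PCQ table violates the schema."""


class GrowthForm(str, enum.Enum):
    GRASS = "grass"
    FORB = "forb"
    WOODY = "woody"


class EcologicalStatus(str, enum.Enum):
    """Grazing-response class of a grass.

    Decreasers are palatable climax grasses that decline under heavy grazing;
    increaser I species are less palatable climax grasses of under-utilised
    veld; increaser II and III species proliferate under moderate to severe
    overgrazing.  Non-grass herbaceous and woody species are classed ``other``.
    """

    DECREASER = "decreaser"
    INCREASER_I = "increaser_I"
    INCREASER_II = "increaser_II"
    INCREASER_III = "increaser_III"
    OTHER = "other"


class Location(str, enum.Enum):
    PLAINS = "plains"
    STREAMS = "streams"
    UPLANDS = "uplands"


class Outcome(str, enum.Enum):
    TUFT_HIT = "tuft_hit"
    BARE_NEAR = "bare_near"
    BARE_PATCH = "bare_patch"


@dataclass(frozen=True)
class SpeciesTrait:
    """Per-species growth form, ecological status and forage factor (0-10)."""

    species_name: str
    growth_form: GrowthForm
    ecological_status: EcologicalStatus
    forage_factor: int

    def __post_init__(self) -> None:
        if not 0 <= self.forage_factor <= 10:
            raise SurveyValidationError(
                f"{self.species_name}: forage_factor {self.forage_factor} "
                "outside [0, 10]"
            )
        if (
            self.growth_form is not GrowthForm.GRASS
            and self.ecological_status is not EcologicalStatus.OTHER
        ):
            raise SurveyValidationError(
                f"{self.species_name}: non-grass species must have "
                "ecological_status 'other'"
            )


@dataclass(frozen=True)
class PointObservation:
    """One rod strike: a tuft hit, a near-bare point, or a wide bare patch.

    ``distance_to_tuft_cm`` is 0 for tuft hits and in (0, 40] for bare_near
    points; bare patches (bare ground wider than 40 cm) carry no species and
    no distance.
    """

    position_m: float
    outcome: Outcome
    species_name: str | None = None
    distance_to_tuft_cm: float | None = None
    longest_axis_cm: float | None = None
    shortest_axis_cm: float | None = None

    def __post_init__(self) -> None:
        if self.outcome is Outcome.TUFT_HIT:
            if not self.species_name:
                raise SurveyValidationError("tuft_hit requires species_name")
            if self.longest_axis_cm is None or self.shortest_axis_cm is None:
                raise SurveyValidationError("tuft_hit requires both tuft axes")
            if not self.longest_axis_cm >= self.shortest_axis_cm > 0:
                raise SurveyValidationError(
                    f"tuft axes must satisfy longest >= shortest > 0, got "
                    f"({self.longest_axis_cm}, {self.shortest_axis_cm})"
                )
            if self.distance_to_tuft_cm not in (None, 0, 0.0):
                raise SurveyValidationError(
                    "tuft_hit distance_to_tuft_cm must be 0"
                )
            object.__setattr__(self, "distance_to_tuft_cm", 0.0)
        elif self.outcome is Outcome.BARE_NEAR:
            if not self.species_name:
                raise SurveyValidationError("bare_near requires species_name")
            if self.distance_to_tuft_cm is None or not (
                0 < self.distance_to_tuft_cm <= 40
            ):
                raise SurveyValidationError(
                    f"bare_near distance must be in (0, 40] cm, got "
                    f"{self.distance_to_tuft_cm}"
                )
            if self.longest_axis_cm is not None or self.shortest_axis_cm is not None:
                raise SurveyValidationError("bare_near carries no tuft axes")
        else:  # BARE_PATCH
            if self.species_name:
                raise SurveyValidationError("bare_patch carries no species")
            if self.distance_to_tuft_cm is not None:
                raise SurveyValidationError("bare_patch carries no distance")

    @property
    def names_species(self) -> bool:
        """True when the point records a species (tuft hit or near-bare)."""
        return self.outcome is not Outcome.BARE_PATCH


@dataclass(frozen=True)
class SiteSurvey:
    """One transect: an ordered run of point observations at a labelled site."""

    site_id: str
    location: Location
    points: tuple[PointObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        positions = [p.position_m for p in self.points]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise SurveyValidationError(
                f"site {self.site_id}: positions must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def species_counts(self) -> dict[str, int]:
        """Occurrence count per species (tuft hits and near-bare records)."""
        counts: dict[str, int] = {}
        for p in self.points:
            if p.names_species:
                counts[p.species_name] = counts.get(p.species_name, 0) + 1
        return counts


@dataclass(frozen=True)
class PCQRecord:
    """Point-centred-quarter record: four tree distances and heights."""

    site_id: str
    location: Location
    point_index: int
    quarter_distances_m: tuple[float, float, float, float]
    heights_m: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "quarter_distances_m", tuple(self.quarter_distances_m)
        )
        object.__setattr__(self, "heights_m", tuple(self.heights_m))
        if len(self.quarter_distances_m) != 4 or len(self.heights_m) != 4:
            raise SurveyValidationError(
                f"site {self.site_id} point {self.point_index}: exactly four "
                "quarters required"
            )
        if any(d <= 0 for d in self.quarter_distances_m):
            raise SurveyValidationError(
                f"site {self.site_id} point {self.point_index}: "
                "quarter distances must be positive"
            )


@dataclass
class AbundanceMatrix:
    """Sites x species occurrence counts with per-site location labels.

    The substrate for diversity indices and Bray-Curtis / ANOSIM / SIMPER.
    """

    site_ids: list[str]
    species_names: list[str]
    counts: np.ndarray  # shape (n_sites, n_species), non-negative ints
    locations: list[Location] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.site_ids), len(self.species_names)):
            raise SurveyValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.species_names)} species"
            )
        if np.any(self.counts < 0):
            raise SurveyValidationError("counts must be non-negative")
        if self.locations and len(self.locations) != len(self.site_ids):
            raise SurveyValidationError("one location label per site required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.site_ids, columns=self.species_names
        )

    def location_labels(self) -> list[str]:
        return [loc.value for loc in self.locations]


# ---------------------------------------------------------------------------
# readers / writers

_TRAIT_COLUMNS = ["species_name", "growth_form", "ecological_status", "forage_factor"]
_SURVEY_COLUMNS = [
    "site_id",
    "location",
    "position_m",
    "outcome",
    "species_name",
    "distance_to_tuft_cm",
    "longest_axis_cm",
    "shortest_axis_cm",
]
_PCQ_COLUMNS = ["site_id", "location", "point_index", "quarter", "distance_m", "height_m"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{what} table missing columns: {missing}")


def read_traits(path: str | Path) -> dict[str, SpeciesTrait]:
    """Read a species-trait CSV into a registry keyed by species name."""
    df = pd.read_csv(path)
    _require_columns(df, _TRAIT_COLUMNS, "traits")
    registry: dict[str, SpeciesTrait] = {}
    for idx, row in df.iterrows():
        try:
            trait = SpeciesTrait(
                species_name=str(row["species_name"]),
                growth_form=GrowthForm(row["growth_form"]),
                ecological_status=EcologicalStatus(row["ecological_status"]),
                forage_factor=int(row["forage_factor"]),
            )
        except (ValueError, SurveyValidationError) as exc:
            raise SurveyValidationError(f"traits row {idx}: {exc}") from exc
        if trait.species_name in registry:
            raise SurveyValidationError(
                f"traits row {idx}: duplicate species {trait.species_name!r}"
            )
        registry[trait.species_name] = trait
    return registry


def write_traits(traits: Mapping[str, SpeciesTrait], path: str | Path) -> None:
    rows = [
        {
            "species_name": t.species_name,
            "growth_form": t.growth_form.value,
            "ecological_status": t.ecological_status.value,
            "forage_factor": t.forage_factor,
        }
        for t in traits.values()
    ]
    pd.DataFrame(rows, columns=_TRAIT_COLUMNS).to_csv(path, index=False)


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_survey(
    path: str | Path, trait_path: str | Path
) -> tuple[list[SiteSurvey], dict[str, SpeciesTrait]]:
    """Read a survey CSV and its trait table.

    Every species named in the survey must resolve to a trait entry; unknown
    species and malformed rows are hard errors that name the offending rows.
    """
    traits = read_traits(trait_path)
    df = pd.read_csv(path)
    _require_columns(df, _SURVEY_COLUMNS, "survey")

    unknown = sorted(
        set(df["species_name"].dropna().astype(str)) - set(traits)
    )
    if unknown:
        raise SurveyValidationError(
            f"survey references species absent from the trait table: {unknown}"
        )

    surveys: list[SiteSurvey] = []
    # groupby(sort=False) preserves file order of sites
    for site_id, site_df in df.groupby("site_id", sort=False):
        locations = site_df["location"].unique()
        if len(locations) != 1:
            raise SurveyValidationError(
                f"site {site_id}: conflicting location labels {list(locations)}"
            )
        points = []
        for idx, row in site_df.iterrows():
            try:
                species = row["species_name"]
                points.append(
                    PointObservation(
                        position_m=float(row["position_m"]),
                        outcome=Outcome(row["outcome"]),
                        species_name=None if pd.isna(species) else str(species),
                        distance_to_tuft_cm=_opt_float(row["distance_to_tuft_cm"]),
                        longest_axis_cm=_opt_float(row["longest_axis_cm"]),
                        shortest_axis_cm=_opt_float(row["shortest_axis_cm"]),
                    )
                )
            except (ValueError, SurveyValidationError) as exc:
                raise SurveyValidationError(f"survey row {idx}: {exc}") from exc
        try:
            surveys.append(
                SiteSurvey(
                    site_id=str(site_id),
                    location=Location(locations[0]),
                    points=tuple(points),
                )
            )
        except (ValueError, SurveyValidationError) as exc:
            raise SurveyValidationError(f"site {site_id}: {exc}") from exc
    return surveys, traits


def write_survey(surveys: Iterable[SiteSurvey], path: str | Path) -> None:
    """Write surveys to the canonical CSV dialect (round-trip safe)."""
    rows = []
    for survey in surveys:
        for p in survey.points:
            rows.append(
                {
                    "site_id": survey.site_id,
                    "location": survey.location.value,
                    "position_m": p.position_m,
                    "outcome": p.outcome.value,
                    "species_name": p.species_name,
                    "distance_to_tuft_cm": p.distance_to_tuft_cm,
                    "longest_axis_cm": p.longest_axis_cm,
                    "shortest_axis_cm": p.shortest_axis_cm,
                }
            )
    pd.DataFrame(rows, columns=_SURVEY_COLUMNS).to_csv(path, index=False)


def read_pcq(path: str | Path) -> list[PCQRecord]:
    """Read a long-format PCQ CSV (one row per quarter) into records."""
    df = pd.read_csv(path)
    _require_columns(df, _PCQ_COLUMNS, "PCQ")
    records: list[PCQRecord] = []
    for (site_id, point_index), grp in df.groupby(
        ["site_id", "point_index"], sort=False
    ):
        grp = grp.sort_values("quarter")
        if list(grp["quarter"]) != [1, 2, 3, 4]:
            raise SurveyValidationError(
                f"site {site_id} point {point_index}: quarters must be 1-4, "
                f"got {list(grp['quarter'])}"
            )
        locations = grp["location"].unique()
        if len(locations) != 1:
            raise SurveyValidationError(
                f"site {site_id}: conflicting location labels {list(locations)}"
            )
        try:
            records.append(
                PCQRecord(
                    site_id=str(site_id),
                    location=Location(locations[0]),
                    point_index=int(point_index),
                    quarter_distances_m=tuple(grp["distance_m"].astype(float)),
                    heights_m=tuple(grp["height_m"].astype(float)),
                )
            )
        except (ValueError, SurveyValidationError) as exc:
            raise SurveyValidationError(
                f"site {site_id} point {point_index}: {exc}"
            ) from exc
    return records


def write_pcq(records: Iterable[PCQRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for quarter, (dist, height) in enumerate(
            zip(rec.quarter_distances_m, rec.heights_m), start=1
        ):
            rows.append(
                {
                    "site_id": rec.site_id,
                    "location": rec.location.value,
                    "point_index": rec.point_index,
                    "quarter": quarter,
                    "distance_m": dist,
                    "height_m": height,
                }
            )
    pd.DataFrame(rows, columns=_PCQ_COLUMNS).to_csv(path, index=False)


def to_abundance_matrix(
    surveys: Sequence[SiteSurvey], count_bare_near: bool = True
) -> AbundanceMatrix:
    """Tabulate per-site species occurrence counts.

    An occurrence is any point that names a species: tuft hits always, and
    near-bare records (the nearest species to a bare point) unless
    ``count_bare_near`` is False.
    """
    if not surveys:
        raise SurveyValidationError("no surveys supplied")
    species: set[str] = set()
    per_site: list[dict[str, int]] = []
    for survey in surveys:
        counts: dict[str, int] = {}
        for p in survey.points:
            if p.outcome is Outcome.TUFT_HIT or (
                count_bare_near and p.outcome is Outcome.BARE_NEAR
            ):
                counts[p.species_name] = counts.get(p.species_name, 0) + 1
        per_site.append(counts)
        species.update(counts)
    names = sorted(species)
    matrix = np.zeros((len(surveys), len(names)), dtype=int)
    index = {name: j for j, name in enumerate(names)}
    for i, counts in enumerate(per_site):
        for name, n in counts.items():
            matrix[i, index[name]] = n
    return AbundanceMatrix(
        site_ids=[s.site_id for s in surveys],
        species_names=names,
        counts=matrix,
        locations=[s.location for s in surveys],
    )
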