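"""Rangeland condition scoring and grazing capacity.

The condition score of a species on a transect is its occurrence count times
its forage factor (a 0-10 index of forage production potential; only grasses
carry non-zero factors).  The transect's veld condition percentage expresses
the summed score relative to a benchmark transect that hits a maximal-forage
species (factor 10) at every point.  Grazing capacity follows the published
linear model

    GC = -0.03 + 0.00289 X1 + (X2 - 419.7) * 0.000633

with X1 the veld condition score (%) and X2 mean annual rainfall (mm), giving
large stock units (LSU, ~450 kg bovine equivalent) per hectare; the
reciprocal, hectares per LSU, is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .field_metrics import transect_basal_cover
from .survey_io import (
    EcologicalStatus,
    GrowthForm,
    SiteSurvey,
    SpeciesTrait,
)

__all__ = [
    "ConditionScoreTable",
    "GrazingCapacityResult",
    "MAX_FORAGE_FACTOR",
    "DEFAULT_RAINFALL_MM",
    "condition_scores",
    "veld_condition_percent",
    "grazing_capacity",
    "site_condition",
    "group_summary",
]

MAX_FORAGE_FACTOR = 10

# mean annual rainfall (mm) of the study rangeland, 1994-2018
DEFAULT_RAINFALL_MM = 661.0


@dataclass(frozen=True)
class ConditionScoreTable:
    """Per-species occurrence x forage-factor scores for one transect."""

    site_id: str
    species: pd.DataFrame  # columns: occurrences, forage_factor, condition_score
    total_score: int
    n_points: int


@dataclass(frozen=True)
class GrazingCapacityResult:
    """Grazing capacity in both unit conventions.

    ``gc_lsu_per_ha`` is the model output (floored at 0); ``ha_per_lsu`` is
    its reciprocal, the area needed to sustain one large stock unit, and is
    None when the floored capacity is 0.
    """

    X1_veld_condition_percent: float
    X2_rainfall_mm: float
    gc_lsu_per_ha: float
    ha_per_lsu: float | None


def _forage_factor(
    species_name: str, traits: Mapping[str, SpeciesTrait]
) -> int:
    """Forage factor for scoring: as supplied for grasses, 0 for non-grasses."""
    trait = traits.get(species_name)
    if trait is None:
        raise KeyError(f"no trait entry for species {species_name!r}")
    if trait.growth_form is not GrowthForm.GRASS:
        return 0
    return trait.forage_factor


def condition_scores(
    survey: SiteSurvey, traits: Mapping[str, SpeciesTrait]
) -> ConditionScoreTable:
    """Per-species condition scores (occurrences x forage factor) for a transect."""
    counts = survey.species_counts()
    missing = sorted(set(counts) - set(traits))
    if missing:
        raise KeyError(
            f"site {survey.site_id}: species without trait entries: {missing}"
        )
    rows = {}
    for name, occ in sorted(counts.items()):
        ff = _forage_factor(name, traits)
        rows[name] = {
            "occurrences": occ,
            "forage_factor": ff,
            "condition_score": occ * ff,
        }
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["occurrences", "forage_factor", "condition_score"],
    ).astype(int) if rows else pd.DataFrame(
        columns=["occurrences", "forage_factor", "condition_score"], dtype=int
    )
    df.index.name = "species_name"
    return ConditionScoreTable(
        site_id=survey.site_id,
        species=df,
        total_score=int(df["condition_score"].sum()) if len(df) else 0,
        n_points=survey.n_points,
    )


def veld_condition_percent(
    table: ConditionScoreTable,
    n_points: int | None = None,
    benchmark_factor: float = MAX_FORAGE_FACTOR,
) -> float:
    """Veld condition score as a percentage of a benchmark transect.

    The benchmark is a transect whose every point hits a species of forage
    factor ``benchmark_factor`` (default 10, the scale maximum), so
    % = 100 * total_score / (n_points * benchmark_factor).
    """
    n = table.n_points if n_points is None else n_points
    if n <= 0:
        raise ValueError("n_points must be positive")
    if benchmark_factor <= 0:
        raise ValueError("benchmark_factor must be positive")
    return 100.0 * table.total_score / (n * benchmark_factor)


def grazing_capacity(
    X1: float, X2: float = DEFAULT_RAINFALL_MM
) -> GrazingCapacityResult:
    """Grazing capacity (LSU/ha and ha/LSU) from veld condition and rainfall.

    The linear model can go negative for poor veld at low rainfall; negative
    capacities are floored at 0 with a warning, and no reciprocal is reported.
    """
    if not 0 <= X1 <= 100:
        raise ValueError(f"veld condition X1 must be in [0, 100], got {X1}")
    if X2 <= 0:
        raise ValueError(f"rainfall X2 must be positive, got {X2}")
    gc = -0.03 + 0.00289 * X1 + (X2 - 419.7) * 0.000633
    if gc <= 0:
        if gc < 0:
            warnings.warn(
                f"grazing capacity {gc:.4f} LSU/ha negative; floored at 0",
                stacklevel=2,
            )
        gc = max(gc, 0.0)
        return GrazingCapacityResult(X1, X2, gc, None)
    return GrazingCapacityResult(X1, X2, float(gc), float(1.0 / gc))


def site_condition(
    survey: SiteSurvey,
    traits: Mapping[str, SpeciesTrait],
    rainfall_mm: float = DEFAULT_RAINFALL_MM,
    benchmark_factor: float = MAX_FORAGE_FACTOR,
) -> dict[str, float]:
    """Convenience chain: scores -> veld condition % -> grazing capacity."""
    table = condition_scores(survey, traits)
    vc = veld_condition_percent(table, benchmark_factor=benchmark_factor)
    gc = grazing_capacity(vc, rainfall_mm)
    return {
        "total_score": table.total_score,
        "veld_condition_percent": vc,
        "gc_lsu_per_ha": gc.gc_lsu_per_ha,
        "ha_per_lsu": gc.ha_per_lsu if gc.ha_per_lsu is not None else float("nan"),
    }


def group_summary(
    surveys: Sequence[SiteSurvey], traits: Mapping[str, SpeciesTrait]
) -> pd.DataFrame:
    """Ecological-group summary of grass observations by location.

    For each (location, ecological status) cell: total occurrences, the share
    of that location's grass occurrences, the encounter rate per survey point,
    and the mean transect basal cover of the location (repeated per group).
    Groups partition grass observations, so shares sum to 1 within a location.
    """
    if not surveys:
        raise ValueError("no surveys supplied")
    rows = []
    site_rows = []
    for survey in surveys:
        counts = survey.species_counts()
        missing = sorted(set(counts) - set(traits))
        if missing:
            raise KeyError(
                f"site {survey.site_id}: species without trait entries: {missing}"
            )
        try:
            bc = transect_basal_cover(survey)
        except ValueError:
            bc = np.nan
        site_rows.append(
            {
                "site_id": survey.site_id,
                "location": survey.location.value,
                "n_points": survey.n_points,
                "basal_cover": bc,
            }
        )
        for name, occ in counts.items():
            trait = traits[name]
            if trait.growth_form is not GrowthForm.GRASS:
                continue
            rows.append(
                {
                    "location": survey.location.value,
                    "group": trait.ecological_status.value,
                    "occurrences": occ,
                }
            )
    if not rows:
        raise ValueError("no grass observations in the supplied surveys")
    df = pd.DataFrame(rows)
    sites_df = pd.DataFrame(site_rows)
    grouped = (
        df.groupby(["location", "group"], sort=True)
        .agg(occurrences=("occurrences", "sum"))
        .reset_index()
    )
    # complete the location x group grid with zero rows
    locations = sorted(sites_df["location"].unique())
    statuses = [s.value for s in EcologicalStatus if s is not EcologicalStatus.OTHER]
    full = pd.MultiIndex.from_product(
        [locations, statuses], names=["location", "group"]
    ).to_frame(index=False)
    grouped = full.merge(grouped, on=["location", "group"], how="left").fillna(
        {"occurrences": 0}
    )
    grouped["occurrences"] = grouped["occurrences"].astype(int)
    loc_totals = grouped.groupby("location")["occurrences"].transform("sum")
    grouped["share_of_grass"] = np.where(
        loc_totals > 0, grouped["occurrences"] / loc_totals, 0.0
    )
    total_points = sites_df.groupby("location")["n_points"].sum()
    grouped["encounter_rate_percent"] = [
        100.0 * occ / total_points[loc]
        for loc, occ in zip(grouped["location"], grouped["occurrences"])
    ]
    mean_bc = sites_df.groupby("location")["basal_cover"].mean()
    grouped["location_mean_basal_cover"] = grouped["location"].map(mean_bc)
    return grouped
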