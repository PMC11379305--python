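"""Per-transect physical metrics: basal cover, encounter rates, tree density.

Basal cover is estimated from the published point-to-tuft regression

    BC = 19.8 + 0.39 D - 11.87 ln(D) + 0.64 d + 2.93 ln(d)

where D is the mean distance (cm) from a survey point to the nearest tuft and
d is the mean basal tuft diameter (cm).  Tree density comes from the
point-centred quarter (PCQ) method with the standard Cottam-Curtis estimator
density = 10000 / rbar^2 trees per hectare, rbar being the mean quarter
distance in metres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .survey_io import Outcome, PCQRecord, SiteSurvey

__all__ = [
    "BasalCoverInput",
    "DensityEstimate",
    "tuft_diameter",
    "basal_cover",
    "transect_basal_cover",
    "encounter_rate",
    "bare_fraction",
    "pcq_density",
    "height_class_frequencies",
    "HEIGHT_CLASS_LABELS",
    "D_MEAN_FLOOR_CM",
]

# mean point-to-tuft distance is floored here so ln(D) stays defined on
# transects where every point is a direct tuft hit (D would otherwise be 0)
D_MEAN_FLOOR_CM = 0.1

HEIGHT_CLASS_LABELS = ("<1 m", "1-2 m", ">2 m")


@dataclass(frozen=True)
class BasalCoverInput:
    """Transect-level means feeding the basal-cover regression (both cm)."""

    D_mean_cm: float
    d_mean_cm: float

    def __post_init__(self) -> None:
        if self.D_mean_cm < 0:
            raise ValueError(f"D_mean_cm must be >= 0, got {self.D_mean_cm}")
        if self.d_mean_cm <= 0:
            raise ValueError(f"d_mean_cm must be > 0, got {self.d_mean_cm}")


@dataclass(frozen=True)
class DensityEstimate:
    """PCQ density estimate: mean quarter distance (m) and trees per hectare."""

    mean_distance_m: float
    trees_per_ha: float


def tuft_diameter(longest_axis_cm: float, shortest_axis_cm: float) -> float:
    """Basal tuft diameter as the arithmetic mean of the two measured axes."""
    if not longest_axis_cm >= shortest_axis_cm > 0:
        raise ValueError(
            f"axes must satisfy longest >= shortest > 0, got "
            f"({longest_axis_cm}, {shortest_axis_cm})"
        )
    return (longest_axis_cm + shortest_axis_cm) / 2.0


def basal_cover(inp: BasalCoverInput) -> float:
    """Percent basal cover from the point-to-tuft regression.

    The regression is unconstrained and can stray outside [0, 100] at extreme
    inputs; the result is clamped there with a warning.
    """
    D, d = inp.D_mean_cm, inp.d_mean_cm
    if D <= 0:
        raise ValueError("D_mean_cm must be > 0 for ln(D); apply the floor first")
    bc = 19.8 + 0.39 * D - 11.87 * np.log(D) + 0.64 * d + 2.93 * np.log(d)
    if bc < 0 or bc > 100:
        warnings.warn(
            f"basal cover {bc:.2f}% outside [0, 100]; clamped", stacklevel=2
        )
        bc = min(max(bc, 0.0), 100.0)
    return float(bc)


def transect_basal_cover(survey: SiteSurvey) -> float:
    """Basal cover (%) of one transect from its mean D and mean d.

    Tuft hits contribute distance 0 to the D mean; near-bare points contribute
    their recorded distance; wide bare patches carry no distance and are
    excluded.  The D mean is floored at ``D_MEAN_FLOOR_CM``.
    """
    distances = [
        p.distance_to_tuft_cm
        for p in survey.points
        if p.outcome in (Outcome.TUFT_HIT, Outcome.BARE_NEAR)
    ]
    diameters = [
        tuft_diameter(p.longest_axis_cm, p.shortest_axis_cm)
        for p in survey.points
        if p.outcome is Outcome.TUFT_HIT
    ]
    if not diameters:
        raise ValueError(
            f"site {survey.site_id}: no tuft hits, no basal measurement possible"
        )
    D_mean = max(float(np.mean(distances)), D_MEAN_FLOOR_CM)
    d_mean = float(np.mean(diameters))
    return basal_cover(BasalCoverInput(D_mean_cm=D_mean, d_mean_cm=d_mean))


def encounter_rate(
    surveys: SiteSurvey | Sequence[SiteSurvey], species_name: str
) -> float:
    """Percent of survey points at which a species is recorded.

    Counts tuft hits and near-bare records naming the species, over all points
    (including bare patches) of the given survey or surveys.
    """
    if isinstance(surveys, SiteSurvey):
        surveys = [surveys]
    total = sum(s.n_points for s in surveys)
    if total == 0:
        raise ValueError("no survey points")
    hits = sum(
        1
        for s in surveys
        for p in s.points
        if p.names_species and p.species_name == species_name
    )
    return 100.0 * hits / total


def bare_fraction(surveys: SiteSurvey | Sequence[SiteSurvey]) -> float:
    """Fraction of points recorded as wide bare patches (>40 cm bare ground)."""
    if isinstance(surveys, SiteSurvey):
        surveys = [surveys]
    total = sum(s.n_points for s in surveys)
    if total == 0:
        raise ValueError("no survey points")
    bare = sum(
        1 for s in surveys for p in s.points if p.outcome is Outcome.BARE_PATCH
    )
    return bare / total


def pcq_density(records: Sequence[PCQRecord]) -> DensityEstimate:
    """Tree density from PCQ quarter distances (Cottam-Curtis estimator).

    density (trees/ha) = 10000 / rbar^2 with rbar the mean of all quarter
    distances in metres.
    """
    if not records:
        raise ValueError("no PCQ records")
    distances = np.array([d for rec in records for d in rec.quarter_distances_m])
    rbar = float(distances.mean())
    return DensityEstimate(mean_distance_m=rbar, trees_per_ha=10000.0 / rbar**2)


def height_class_frequencies(records: Sequence[PCQRecord]) -> dict[str, float]:
    """Proportion of trees in the height classes <1 m, 1-2 m and >2 m.

    Classes are half-open and lower-inclusive: [0, 1), [1, 2), [2, inf).
    """
    if not records:
        raise ValueError("no PCQ records")
    heights = np.array([h for rec in records for h in rec.heights_m])
    if np.any(heights <= 0):
        raise ValueError("tree heights must be positive")
    counts = np.array(
        [
            np.sum(heights < 1.0),
            np.sum((heights >= 1.0) & (heights < 2.0)),
            np.sum(heights >= 2.0),
        ]
    )
    props = counts / heights.size
    return dict(zip(HEIGHT_CLASS_LABELS, props.tolist()))
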