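"""Synthetic rangeland survey generator.

No field data accompany the study design this package analyses, so every
pipeline stage is exercised on simulated surveys that carry the same
statistical structure: three topographic locations (plains, streams,
uplands) with location-specific species relative abundances, bare-ground
fractions, tuft-size distributions and, for the woody layer, point-centred
quarter (PCQ) tree distances and height mixtures.

Each transect point independently draws an outcome (tuft hit / bare ground
near a tuft / wide bare patch); species-naming points draw a species from
the location's abundance simplex; tuft axes come from a log-normal diameter
with a half-normal axis asymmetry (so longest >= shortest by construction);
bare distances come from a log-normal truncated at the 40 cm rule — draws
beyond 40 cm are re-coded as wide bare patches, exactly as a field recorder
would class them.

``paper_like_scenario`` encodes the qualitative structure of the motivating
survey: 15 sites per location, 50 points per transect, an Aristida-like
increaser III dominant at 0.34 relative abundance in plains, a
Sporobolus-like dominant at 0.29 in streams, and decreaser grasses present
only in plains (at low abundance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .survey_io import (
    EcologicalStatus,
    GrowthForm,
    Location,
    Outcome,
    PCQRecord,
    PointObservation,
    SiteSurvey,
    SpeciesTrait,
)

__all__ = [
    "LocationCommunity",
    "CommunitySpec",
    "LocationPCQ",
    "PCQSpec",
    "simulate_survey",
    "simulate_pcq",
    "paper_like_scenario",
    "paper_like_pcq_scenario",
    "paper_like_traits",
    "spec_to_json",
    "spec_from_json",
    "BARE_PATCH_THRESHOLD_CM",
]

BARE_PATCH_THRESHOLD_CM = 40.0


@dataclass(frozen=True)
class LocationCommunity:
    """Sampling model of one topographic location.

    ``abundances`` is a species -> relative abundance simplex;
    ``p_bare_near`` / ``p_bare_patch`` are nominal per-point probabilities of
    the two bare outcomes (tuft hits take the remainder);
    ``tuft_diam_mu`` / ``tuft_diam_sigma`` parameterise a log-normal basal
    diameter in cm (mu, sigma on the log scale);
    ``bare_dist_mu`` / ``bare_dist_sigma`` likewise for the bare-point
    distance to the nearest tuft, truncated at 40 cm (exceedances are
    re-coded as wide bare patches).
    """

    abundances: Mapping[str, float]
    p_bare_near: float = 0.16
    p_bare_patch: float = 0.04
    tuft_diam_mu: float = np.log(8.0)
    tuft_diam_sigma: float = 0.4
    bare_dist_mu: float = np.log(12.0)
    bare_dist_sigma: float = 0.6

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"abundances must sum to 1, got {total}")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if not (0 <= self.p_bare_near <= 1 and 0 <= self.p_bare_patch <= 1):
            raise ValueError("bare probabilities must lie in [0, 1]")
        if self.p_bare_near + self.p_bare_patch > 1:
            raise ValueError("hit probability would be negative")

    @property
    def p_hit(self) -> float:
        return 1.0 - self.p_bare_near - self.p_bare_patch


@dataclass(frozen=True)
class CommunitySpec:
    """Full survey design: one community model per location."""

    communities: Mapping[Location, LocationCommunity]
    sites_per_location: int = 15
    points_per_transect: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_location < 1 or self.points_per_transect < 1:
            raise ValueError("sites and points counts must be positive")
        if not self.communities:
            raise ValueError("at least one location community required")


@dataclass(frozen=True)
class LocationPCQ:
    """PCQ sampling model: log-normal tree distances, height-class mixture."""

    dist_mu: float = np.log(1.2)
    dist_sigma: float = 0.5
    height_weights: tuple[float, float, float] = (0.68, 0.22, 0.10)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.height_weights), 1.0, atol=1e-8):
            raise ValueError("height weights must sum to 1")
        if any(w < 0 for w in self.height_weights):
            raise ValueError("height weights must be non-negative")


@dataclass(frozen=True)
class PCQSpec:
    models: Mapping[Location, LocationPCQ]
    points_per_site: int = 10
    sites_per_location: int = 15
    seed: int = 0


def _draw_tuft_axes(
    rng: np.random.Generator, mu: float, sigma: float
) -> tuple[float, float]:
    """Axes as (m + |delta|, m - |delta|) around a log-normal mean diameter."""
    m = float(rng.lognormal(mu, sigma))
    delta = abs(float(rng.normal(0.0, 0.15 * m)))
    delta = min(delta, 0.9 * m)  # keep the short axis positive
    return round(m + delta, 2), round(m - delta, 2)


def simulate_survey(spec: CommunitySpec) -> list[SiteSurvey]:
    """Generate seeded transect surveys under a community specification.

    Identical spec and seed give identical output.  Every generated survey
    satisfies the survey-table invariants by construction.
    """
    rng = np.random.default_rng(spec.seed)
    surveys: list[SiteSurvey] = []
    for location, community in spec.communities.items():
        species = list(community.abundances.keys())
        probs = np.array([community.abundances[s] for s in species])
        for k in range(spec.sites_per_location):
            site_id = f"{location.value}-{k + 1:02d}"
            points = []
            for pos in range(spec.points_per_transect):
                u = rng.random()
                if u < community.p_bare_patch:
                    outcome = Outcome.BARE_PATCH
                elif u < community.p_bare_patch + community.p_bare_near:
                    outcome = Outcome.BARE_NEAR
                else:
                    outcome = Outcome.TUFT_HIT
                if outcome is Outcome.BARE_NEAR:
                    dist = float(
                        rng.lognormal(community.bare_dist_mu, community.bare_dist_sigma)
                    )
                    if dist > BARE_PATCH_THRESHOLD_CM:
                        # beyond the 40 cm rule: the recorder classes this
                        # point as a wide bare patch
                        outcome = Outcome.BARE_PATCH
                    else:
                        dist = max(round(dist, 1), 0.1)
                if outcome is Outcome.BARE_PATCH:
                    points.append(
                        PointObservation(position_m=float(pos), outcome=outcome)
                    )
                    continue
                name = species[int(rng.choice(len(species), p=probs))]
                if outcome is Outcome.TUFT_HIT:
                    longest, shortest = _draw_tuft_axes(
                        rng, community.tuft_diam_mu, community.tuft_diam_sigma
                    )
                    points.append(
                        PointObservation(
                            position_m=float(pos),
                            outcome=outcome,
                            species_name=name,
                            longest_axis_cm=longest,
                            shortest_axis_cm=shortest,
                        )
                    )
                else:
                    points.append(
                        PointObservation(
                            position_m=float(pos),
                            outcome=outcome,
                            species_name=name,
                            distance_to_tuft_cm=dist,
                        )
                    )
            surveys.append(
                SiteSurvey(site_id=site_id, location=location, points=tuple(points))
            )
    return surveys


def simulate_pcq(spec: PCQSpec) -> list[PCQRecord]:
    """Generate seeded PCQ tree records (four quarters per point)."""
    rng = np.random.default_rng(spec.seed)
    # representative heights within each class: <1 m, 1-2 m, >2 m
    records: list[PCQRecord] = []
    for location, model in spec.models.items():
        weights = np.asarray(model.height_weights)
        for k in range(spec.sites_per_location):
            site_id = f"{location.value}-{k + 1:02d}"
            for point in range(spec.points_per_site):
                dists = rng.lognormal(model.dist_mu, model.dist_sigma, size=4)
                classes = rng.choice(3, size=4, p=weights)
                heights = np.empty(4)
                for q, c in enumerate(classes):
                    if c == 0:
                        heights[q] = rng.uniform(0.2, 1.0 - 1e-6)
                    elif c == 1:
                        heights[q] = rng.uniform(1.0, 2.0 - 1e-6)
                    else:
                        heights[q] = 2.0 + rng.exponential(0.8)
                records.append(
                    PCQRecord(
                        site_id=site_id,
                        location=location,
                        point_index=point,
                        quarter_distances_m=tuple(np.round(dists, 3)),
                        heights_m=tuple(np.round(heights, 3)),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# default scenario


_SCENARIO_TRAITS: list[tuple[str, str, str, int]] = [
    # (species, growth form, ecological status, forage factor)
    ("Themeda triandra", "grass", "decreaser", 10),
    ("Monocymbium ceresiiforme", "grass", "decreaser", 7),
    ("Digitaria tricholaenoides", "grass", "decreaser", 7),
    ("Setaria sphacelata", "grass", "decreaser", 8),
    ("Heteropogon contortus", "grass", "increaser_I", 7),
    ("Hyparrhenia hirta", "grass", "increaser_I", 5),
    ("Festuca costata", "grass", "increaser_I", 4),
    ("Eragrostis curvula", "grass", "increaser_II", 5),
    ("Eragrostis plana", "grass", "increaser_II", 2),
    ("Eragrostis racemosa", "grass", "increaser_II", 3),
    ("Eragrostis gummiflua", "grass", "increaser_II", 2),
    ("Cynodon dactylon", "grass", "increaser_II", 6),
    ("Urochloa panicoides", "grass", "increaser_II", 3),
    ("Andropogon eucomis", "grass", "increaser_II", 3),
    ("Aristida junciformis", "grass", "increaser_III", 1),
    ("Sporobolus africanus", "grass", "increaser_III", 2),
    ("Aristida diffusa", "grass", "increaser_III", 1),
    ("Aristida congesta", "grass", "increaser_III", 1),
    ("Rendlia altera", "grass", "increaser_II", 3),
    ("Richardia brasiliensis", "forb", "other", 0),
    ("Felicia sp.", "forb", "other", 0),
    ("Helichrysum sp.", "forb", "other", 0),
    ("Senecio sp.", "forb", "other", 0),
    ("Leucosidea sericea", "woody", "other", 0),
    ("Diospyros lycioides", "woody", "other", 0),
    ("Buddleja salviifolia", "woody", "other", 0),
]


def paper_like_traits() -> dict[str, SpeciesTrait]:
    """Trait registry for the default synthetic scenario.

    Species names and ecological-status classes follow the flora of
    high-altitude East Griqualand grassland; forage factors are synthetic but
    field-plausible (palatable decreasers high, wiry increaser III grasses
    low, forbs and woody plants 0).
    """
    return {
        name: SpeciesTrait(
            species_name=name,
            growth_form=GrowthForm(gf),
            ecological_status=EcologicalStatus(es),
            forage_factor=ff,
        )
        for name, gf, es, ff in _SCENARIO_TRAITS
    }


def paper_like_scenario(seed: int = 0) -> CommunitySpec:
    """Default synthetic survey design: 15 sites x 3 locations x 50 points.

    Plains hold the largest species pool (22 species) including all four
    decreasers; streams (19 species) and uplands (16 species) lack decreasers
    and include the woody encroacher.  Dominants and their abundances mirror
    the published encounter rates qualitatively: an Aristida-like increaser
    III at 0.34 in plains, a Sporobolus-like increaser III at 0.29 in
    streams.
    """
    plains = {
        "Aristida junciformis": 0.34,
        "Sporobolus africanus": 0.18,
        "Eragrostis curvula": 0.10,
        "Eragrostis gummiflua": 0.06,
        "Urochloa panicoides": 0.05,
        "Andropogon eucomis": 0.04,
        "Monocymbium ceresiiforme": 0.03,
        "Hyparrhenia hirta": 0.03,
        "Heteropogon contortus": 0.03,
        "Eragrostis racemosa": 0.025,
        "Cynodon dactylon": 0.02,
        "Themeda triandra": 0.019,
        "Digitaria tricholaenoides": 0.015,
        "Setaria sphacelata": 0.012,
        "Aristida congesta": 0.012,
        "Aristida diffusa": 0.01,
        "Rendlia altera": 0.01,
        "Festuca costata": 0.008,
        "Richardia brasiliensis": 0.02,
        "Felicia sp.": 0.012,
        "Helichrysum sp.": 0.01,
        "Senecio sp.": 0.007,
    }
    streams = {
        "Sporobolus africanus": 0.29,
        "Eragrostis plana": 0.17,
        "Eragrostis curvula": 0.12,
        "Aristida junciformis": 0.07,
        "Leucosidea sericea": 0.08,
        "Hyparrhenia hirta": 0.04,
        "Heteropogon contortus": 0.035,
        "Cynodon dactylon": 0.03,
        "Eragrostis racemosa": 0.03,
        "Aristida diffusa": 0.022,
        "Rendlia altera": 0.02,
        "Festuca costata": 0.015,
        "Urochloa panicoides": 0.012,
        "Aristida congesta": 0.011,
        "Diospyros lycioides": 0.03,
        "Richardia brasiliensis": 0.03,
        "Felicia sp.": 0.025,
        "Helichrysum sp.": 0.02,
        "Senecio sp.": 0.01,
    }
    uplands = {
        "Aristida junciformis": 0.16,
        "Eragrostis curvula": 0.15,
        "Eragrostis plana": 0.14,
        "Sporobolus africanus": 0.096,
        "Leucosidea sericea": 0.12,
        "Heteropogon contortus": 0.06,
        "Eragrostis racemosa": 0.05,
        "Hyparrhenia hirta": 0.04,
        "Aristida diffusa": 0.035,
        "Rendlia altera": 0.03,
        "Festuca costata": 0.025,
        "Aristida congesta": 0.019,
        "Buddleja salviifolia": 0.02,
        "Richardia brasiliensis": 0.025,
        "Felicia sp.": 0.02,
        "Helichrysum sp.": 0.01,
    }
    communities = {}
    for location, abundances in (
        (Location.PLAINS, plains),
        (Location.STREAMS, streams),
        (Location.UPLANDS, uplands),
    ):
        total = sum(abundances.values())
        abundances = {k: v / total for k, v in abundances.items()}
        communities[location] = LocationCommunity(abundances=abundances)
    return CommunitySpec(communities=communities, seed=seed)


def paper_like_pcq_scenario(seed: int = 0) -> PCQSpec:
    """Default woody-layer design: dense short encroachment stands.

    Streams carry the 68% short-tree (<1 m) share and uplands the 49% share
    reported for the encroacher's height structure; plains are excluded (the
    open grassland holds no encroacher stands).
    """
    return PCQSpec(
        models={
            Location.STREAMS: LocationPCQ(
                dist_mu=np.log(1.2), dist_sigma=0.45,
                height_weights=(0.68, 0.22, 0.10),
            ),
            Location.UPLANDS: LocationPCQ(
                dist_mu=np.log(1.1), dist_sigma=0.45,
                height_weights=(0.49, 0.33, 0.18),
            ),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# JSON (de)serialisation of specs, for the CLI


def spec_to_json(spec: CommunitySpec, path: str | Path) -> None:
    payload = {
        "sites_per_location": spec.sites_per_location,
        "points_per_transect": spec.points_per_transect,
        "seed": spec.seed,
        "communities": {
            loc.value: {
                "abundances": dict(c.abundances),
                "p_bare_near": c.p_bare_near,
                "p_bare_patch": c.p_bare_patch,
                "tuft_diam_mu": c.tuft_diam_mu,
                "tuft_diam_sigma": c.tuft_diam_sigma,
                "bare_dist_mu": c.bare_dist_mu,
                "bare_dist_sigma": c.bare_dist_sigma,
            }
            for loc, c in spec.communities.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def spec_from_json(path: str | Path) -> CommunitySpec:
    payload = json.loads(Path(path).read_text())
    communities = {
        Location(loc): LocationCommunity(**fields)
        for loc, fields in payload["communities"].items()
    }
    return CommunitySpec(
        communities=communities,
        sites_per_location=payload.get("sites_per_location", 15),
        points_per_transect=payload.get("points_per_transect", 50),
        seed=payload.get("seed", 0),
    )
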