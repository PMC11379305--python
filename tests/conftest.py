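import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from veldscore.survey_io import (
    EcologicalStatus,
    GrowthForm,
    Location,
    Outcome,
    PointObservation,
    SiteSurvey,
    SpeciesTrait,
)


def make_trait(name, growth_form="grass", status="increaser_II", ff=5):
    return SpeciesTrait(
        species_name=name,
        growth_form=GrowthForm(growth_form),
        ecological_status=EcologicalStatus(status),
        forage_factor=ff,
    )


def hit(pos, species, longest=10.0, shortest=8.0):
    return PointObservation(
        position_m=float(pos),
        outcome=Outcome.TUFT_HIT,
        species_name=species,
        longest_axis_cm=longest,
        shortest_axis_cm=shortest,
    )


def bare_near(pos, species, distance):
    return PointObservation(
        position_m=float(pos),
        outcome=Outcome.BARE_NEAR,
        species_name=species,
        distance_to_tuft_cm=distance,
    )


def bare_patch(pos):
    return PointObservation(position_m=float(pos), outcome=Outcome.BARE_PATCH)


@pytest.fixture
def simple_traits():
    return {
        "A": make_trait("A", status="decreaser", ff=7),
        "B": make_trait("B", status="increaser_II", ff=5),
        "C": make_trait("C", status="increaser_III", ff=2),
        "F": make_trait("F", growth_form="forb", status="other", ff=0),
    }


@pytest.fixture
def mixed_survey():
    """Ten points: 6 tuft hits, 2 near-bare, 2 wide bare patches."""
    points = (
        hit(0, "A"),
        hit(1, "A"),
        hit(2, "B"),
        bare_near(3, "A", 12.0),
        hit(4, "C"),
        bare_patch(5),
        hit(6, "B"),
        bare_near(7, "C", 30.0),
        bare_patch(8),
        hit(9, "A"),
    )
    return SiteSurvey(site_id="s1", location=Location.PLAINS, points=points)
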