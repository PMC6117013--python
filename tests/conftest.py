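from datetime import date, timedelta

import pytest

from scp_reclass import (
    DEFAULT_CATALOG,
    DispensingRecord,
    GeneratorConfig,
    PerinatalRecord,
    classify_cohort,
    derive_episode,
    generate,
)


@pytest.fixture(scope="session")
def catalog():
    return DEFAULT_CATALOG


@pytest.fixture
def make_perinatal():
    """Factory for perinatal records with sensible defaults."""

    def _make(
        pregnancy_id="P1",
        woman_id="W1",
        delivery_date=date(2012, 6, 1),
        gestation_weeks=39,
        smoked_any=False,
        smoked_first_half=None,
        smoked_second_half=None,
        maternal_age=28,
        marital_status="not_married",
        seifa_quintile=3,
        hospital_type="public",
        state="NSW",
    ):
        return PerinatalRecord(
            pregnancy_id=pregnancy_id,
            woman_id=woman_id,
            delivery_date=delivery_date,
            gestation_weeks=gestation_weeks,
            smoked_any=smoked_any,
            smoked_first_half=smoked_first_half,
            smoked_second_half=smoked_second_half,
            maternal_age=maternal_age,
            marital_status=marital_status,
            seifa_quintile=seifa_quintile,
            hospital_type=hospital_type,
            state=state,
        )

    return _make


@pytest.fixture
def make_episode(make_perinatal):
    def _make(**kwargs):
        return derive_episode(make_perinatal(**kwargs))

    return _make


@pytest.fixture
def make_supply():
    """Factory for a dispensing record at an offset before conception.

    ``days_before_conception`` > 0 places the supply before conception.
    """

    def _make(
        episode,
        days_before_conception,
        days,
        atc="N07BA03",
        woman_id=None,
        concession="concessional",
    ):
        spec = DEFAULT_CATALOG[atc]
        return DispensingRecord(
            woman_id=woman_id or episode.woman_id,
            supply_date=episode.conception_date - timedelta(days=days_before_conception),
            atc_code=atc,
            quantity=days * spec.doses_per_day,
            concession_status=concession,
        )

    return _make


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-condition cohort at n = 10,000 used across test modules."""
    return generate(GeneratorConfig(n_women=10_000, seed=11))


@pytest.fixture(scope="session")
def classified_cohort(synthetic_cohort):
    c = synthetic_cohort
    return classify_cohort(c.perinatal, c.hospital, c.dispensing)
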