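import math
import random
from datetime import timedelta

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from scp_reclass import (
    DEFAULT_CATALOG,
    build_course,
    days_covered,
    exposed_during_pregnancy,
    mpr,
)


def course_from_offsets(make_episode, make_supply, offsets_days, atc="N07BA03"):
    """Build a course from (days_before_conception, days_covered) pairs."""
    ep = make_episode()
    supplies = [make_supply(ep, off, days, atc=atc) for off, days in offsets_days]
    return ep, build_course(ep, supplies, DEFAULT_CATALOG)


class TestDaysCovered:
    @pytest.mark.parametrize(
        "quantity, atc, expected",
        [
            (56, "N07BA03", 28.0),  # varenicline, twice daily
            (28, "N07BA01", 28.0),  # NRT patches, once daily
            (1, "N07BA02", 0.5),  # bupropion, fractional days carried
        ],
    )
    def test_quantity_over_daily_doses(self, quantity, atc, expected):
        assert days_covered(quantity, DEFAULT_CATALOG[atc]) == expected

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            days_covered(0, DEFAULT_CATALOG["N07BA01"])


class TestBuildCourse:
    def test_supply_outside_lookback_window_excluded(self, make_episode, make_supply):
        ep, course = course_from_offsets(make_episode, make_supply, [(150, 28)])
        assert course is None

    def test_supply_at_window_boundaries_included(self, make_episode, make_supply):
        ep = make_episode()
        at_start = make_supply(ep, 100, 28)
        after_delivery = make_supply(
            ep, (ep.conception_date - ep.delivery_date).days - 1, 28
        )
        assert build_course(ep, [at_start], DEFAULT_CATALOG) is not None
        assert build_course(ep, [after_delivery], DEFAULT_CATALOG) is None

    def test_two_supplies_pooled(self, make_episode, make_supply):
        ep, course = course_from_offsets(make_episode, make_supply, [(50, 28), (20, 28)])
        assert course.total_days_supplied == 56
        assert course.index_supply.supply_date == ep.conception_date - timedelta(days=50)
        assert course.n_supplies == 2

    def test_single_supply_degenerate(self, make_episode, make_supply):
        _, course = course_from_offsets(make_episode, make_supply, [(30, 28)])
        assert course.final_supply == course.index_supply

    def test_non_catalog_atc_ignored(self, make_episode, make_supply):
        ep = make_episode()
        rec = make_supply(ep, 30, 28, atc="N07BA03")
        other = rec.__class__(
            woman_id=rec.woman_id,
            supply_date=rec.supply_date,
            atc_code="J01CA04",
            quantity=20,
            concession_status="general",
        )
        course = build_course(ep, [other], DEFAULT_CATALOG)
        assert course is None
        course = build_course(ep, [other, rec], DEFAULT_CATALOG)
        assert course.n_supplies == 1

    def test_pooling_is_order_independent(self, make_episode, make_supply):
        ep = make_episode()
        supplies = [
            make_supply(ep, off, d, atc=atc)
            for off, d, atc in [(90, 14, "N07BA01"), (90, 28, "N07BA02"), (40, 28, "N07BA03"), (10, 7, "N07BA01")]
        ]
        reference = build_course(ep, supplies, DEFAULT_CATALOG)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = supplies[:]
            rng.shuffle(shuffled)
            assert build_course(ep, shuffled, DEFAULT_CATALOG) == reference

    def test_same_date_tie_breaks_on_atc(self, make_episode, make_supply):
        ep = make_episode()
        supplies = [
            make_supply(ep, 50, 28, atc="N07BA03"),
            make_supply(ep, 50, 28, atc="N07BA01"),
        ]
        course = build_course(ep, supplies, DEFAULT_CATALOG)
        assert course.index_supply.atc_code == "N07BA01"


class TestMpr:
    def test_single_supply_is_exactly_100(self, make_episode, make_supply):
        _, course = course_from_offsets(make_episode, make_supply, [(30, 28)])
        assert mpr(course) == 100.0

    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ([(60, 28), (30, 28)], 100 * 56 / 58),  # gap of 2 days
            ([(90, 14), (30, 14)], 100 * 28 / 74),  # long gap, low adherence
        ],
    )
    def test_hand_evaluated_values(self, make_episode, make_supply, pattern, expected):
        _, course = course_from_offsets(make_episode, make_supply, pattern)
        assert mpr(course) == pytest.approx(expected)

    def test_overlapping_supplies_exceed_100(self, make_episode, make_supply):
        _, course = course_from_offsets(make_episode, make_supply, [(60, 28), (50, 28)])
        assert mpr(course) > 100

    @given(
        first_days=st.integers(1, 20),
        gap=st.integers(0, 15),
        last_days=st.integers(1, 20),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_consistency(self, first_days, gap, last_days):
        # doubling every duration and gap leaves the ratio unchanged
        def ratio(scale):
            total = scale * (first_days + last_days)
            span = scale * (first_days + gap) + scale * last_days
            return 100 * total / span

        assert ratio(1) == pytest.approx(ratio(2))


class TestExposedDuringPregnancy:
    def test_supply_after_conception_is_exposed(self, make_episode, make_supply):
        ep, course = course_from_offsets(make_episode, make_supply, [(-1, 28)])
        assert exposed_during_pregnancy(ep, course)

    def test_coverage_ending_exactly_at_conception_not_exposed(
        self, make_episode, make_supply
    ):
        ep, course = course_from_offsets(make_episode, make_supply, [(28, 28)])
        assert not exposed_during_pregnancy(ep, course)

    def test_two_early_short_supplies_not_exposed(self, make_episode, make_supply):
        # condition (i): last supply ends 6 days before conception;
        # condition (ii): index + 28 days ends 62 days before conception
        ep, course = course_from_offsets(make_episode, make_supply, [(90, 14), (20, 14)])
        assert not exposed_during_pregnancy(ep, course)

    def test_monotone_under_later_shifts(self, make_episode, make_supply):
        pattern = [(90, 14), (40, 14)]
        ep, course = course_from_offsets(make_episode, make_supply, pattern)
        exposed_states = []
        for shift in range(0, 90, 10):
            shifted = [(off - shift, d) for off, d in pattern]
            _, c = course_from_offsets(make_episode, make_supply, shifted)
            exposed_states.append(exposed_during_pregnancy(ep, c))
        # once true, shifting later never flips back to false
        assert exposed_states == sorted(exposed_states)

    @given(
        offsets=st.lists(
            st.tuples(st.integers(-50, 100), st.integers(1, 60)), min_size=1, max_size=5
        )
    )
    @settings(
        deadline=None,
        max_examples=100,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_matches_literal_two_clause_transcription(
        self, make_episode, make_supply, offsets
    ):
        ep, course = course_from_offsets(make_episode, make_supply, offsets)
        if course is None:
            return
        conception = ep.conception_date
        clause_i = any(
            (s.supply_date - conception).days + s.days_covered > 0
            for s in course.supplies
        )
        clause_ii = (
            (course.index_supply.supply_date - conception).days
            + course.total_days_supplied
            > 0
        )
        assert exposed_during_pregnancy(ep, course) == (clause_i or clause_ii)
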