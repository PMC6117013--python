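import itertools

import pytest

from scp_reclass import (
    DEFAULT_CATALOG,
    RecordedStatus,
    build_course,
    cascade_counts,
    classify,
    criterion_duration,
    criterion_mpr,
    criterion_timing,
)


def course(make_episode, make_supply, pattern, atc="N07BA03"):
    ep = make_episode()
    supplies = [make_supply(ep, off, d, atc=atc) for off, d in pattern]
    return ep, build_course(ep, supplies, DEFAULT_CATALOG)


def status(pid="P1", perinatal=False, hospital=False, missing=False):
    return RecordedStatus(pid, perinatal, hospital, missing)


class TestCriteria:
    @pytest.mark.parametrize(
        "atc, offset, expected",
        [
            ("N07BA03", 7, True),  # varenicline exactly one week: closed boundary
            ("N07BA03", 6, False),
            ("N07BA01", 13, False),  # NRT needs two weeks
            ("N07BA01", 14, True),
            ("N07BA02", -5, False),  # bupropion index after conception
        ],
    )
    def test_timing_lead_time_boundaries(self, make_episode, make_supply, atc, offset, expected):
        ep, c = course(make_episode, make_supply, [(offset, 28)], atc=atc)
        assert criterion_timing(c, ep, DEFAULT_CATALOG) is expected

    @pytest.mark.parametrize(
        "atc, total, expected",
        [
            ("N07BA03", 84, True),  # 12 weeks varenicline
            ("N07BA01", 55, False),  # one day short of 8 weeks NRT
            ("N07BA01", 56, True),
            ("N07BA02", 49, True),  # 7 weeks bupropion, closed boundary
        ],
    )
    def test_duration_minimum_course(self, make_episode, make_supply, atc, total, expected):
        # consecutive supplies so only the total is at stake
        pattern = [(90, total / 2), (90 - total / 2, total / 2)]
        _, c = course(make_episode, make_supply, pattern, atc=atc)
        assert c.total_days_supplied == pytest.approx(total)
        assert criterion_duration(c, DEFAULT_CATALOG) is expected

    def test_mpr_single_supply_passes(self, make_episode, make_supply):
        _, c = course(make_episode, make_supply, [(30, 28)])
        assert c.mpr == 100.0
        assert criterion_mpr(c)

    def test_mpr_exactly_80_passes(self, make_episode, make_supply):
        # 28 d at day 0 and day 42: 100 * 56 / 70 = 80 exactly
        _, c = course(make_episode, make_supply, [(90, 28), (48, 28)])
        assert c.mpr == pytest.approx(80.0)
        assert criterion_mpr(c)

    def test_mpr_low_adherence_fails(self, make_episode, make_supply):
        _, c = course(make_episode, make_supply, [(90, 14), (30, 14)])
        assert c.mpr == pytest.approx(100 * 28 / 74)
        assert not criterion_mpr(c)


FULL_PASS = [(70, 28), (42, 28), (14, 28)]  # timely, 84 d, MPR 100, covers conception
LATE_START = [(3, 28)]


class TestClassify:
    def test_all_criteria_pass_maintains_non_smoking(self, make_episode, make_supply):
        ep, c = course(make_episode, make_supply, FULL_PASS)
        res = classify(ep, c, status(), DEFAULT_CATALOG)
        assert res.exposed and not res.final_smoking and not res.reclassified
        assert res.failing_criterion == "none"

    def test_timing_failure_reclassifies(self, make_episode, make_supply):
        ep, c = course(make_episode, make_supply, LATE_START)
        res = classify(ep, c, status(), DEFAULT_CATALOG)
        assert res.reclassified and res.final_smoking
        assert res.failing_criterion == "timing"

    def test_unexposed_keeps_recorded_status(self, make_episode):
        ep = make_episode()
        res = classify(ep, None, status(perinatal=True), DEFAULT_CATALOG)
        assert res.final_smoking and not res.exposed
        assert res.c1_timing is None and res.failing_criterion == "none"

    def test_exposed_recorded_smoker_bypasses_cascade(self, make_episode, make_supply):
        ep, c = course(make_episode, make_supply, LATE_START)
        res = classify(ep, c, status(perinatal=True), DEFAULT_CATALOG)
        assert res.final_smoking and not res.reclassified
        assert res.c1_timing is None

    def test_pre_conception_course_not_exposed(self, make_episode, make_supply):
        ep, c = course(make_episode, make_supply, [(90, 28)])
        res = classify(ep, c, status(), DEFAULT_CATALOG)
        assert not res.exposed and not res.final_smoking

    @pytest.mark.parametrize(
        "pattern",
        [LATE_START, [(10, 28)], [(20, 90), (-60, 28)], FULL_PASS],
    )
    def test_reclassified_flag_invariant_under_all_orderings(
        self, make_episode, make_supply, pattern
    ):
        ep, c = course(make_episode, make_supply, pattern)
        outcomes = {
            classify(ep, c, status(), DEFAULT_CATALOG, order=perm).reclassified
            for perm in itertools.permutations(("timing", "duration", "mpr"))
        }
        assert len(outcomes) == 1

    def test_classification_is_deterministic(self, make_episode, make_supply):
        ep, c = course(make_episode, make_supply, LATE_START)
        assert classify(ep, c, status(), DEFAULT_CATALOG) == classify(
            ep, c, status(), DEFAULT_CATALOG
        )


class TestCascadeCounts:
    def test_empty_input_all_zeros(self):
        counts = cascade_counts([])
        assert all(v == 0 for v in counts.values())

    def test_conservation_identity(self, classified_cohort):
        c = cascade_counts(classified_cohort.results)
        assert c["n_exposed_unrecorded"] == (
            c["fail_timing"]
            + c["fail_duration_given_timing_pass"]
            + c["fail_mpr_given_both_pass"]
            + c["maintained"]
        )
        assert c["reclassified_total"] == (
            c["fail_timing"]
            + c["fail_duration_given_timing_pass"]
            + c["fail_mpr_given_both_pass"]
        )

    def test_counts_match_generator_truth(self, synthetic_cohort, classified_cohort):
        truth = synthetic_cohort.truth.set_index("pregnancy_id")
        unrecorded = [
            r for r in classified_cohort.results if r.exposed and not r.recorded_smoking
        ]
        scenario_of = truth["scenario"]
        expected = {
            "timing": sum(
                scenario_of[r.pregnancy_id] == "continuing_late_start" for r in unrecorded
            ),
            "duration": sum(
                scenario_of[r.pregnancy_id] == "continuing_short_course" for r in unrecorded
            ),
            "mpr": sum(
                scenario_of[r.pregnancy_id] == "continuing_low_mpr" for r in unrecorded
            ),
            "none": sum(
                scenario_of[r.pregnancy_id] == "quitter_full_course" for r in unrecorded
            ),
        }
        c = cascade_counts(classified_cohort.results)
        assert c["fail_timing"] == expected["timing"]
        assert c["fail_duration_given_timing_pass"] == expected["duration"]
        assert c["fail_mpr_given_both_pass"] == expected["mpr"]
        assert c["maintained"] == expected["none"]
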