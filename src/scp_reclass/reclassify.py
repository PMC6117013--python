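"""The reclassification cascade for exposed pregnancies without a smoking record.

A pregnancy exposed to smoking cessation pharmacotherapy but with no
recorded smoking is either a successful pre-conception quit attempt
(non-smoking status maintained) or an under-reported smoker.  The
cascade keeps the non-smoking record only when all three of the
following hold, and reclassifies the woman as smoking otherwise:

1. *Timing* — the index supply preceded conception by at least the
   therapy's lead time (one week for varenicline/bupropion, two weeks
   for NRT).
2. *Duration* — the total days of supply reached the minimum
   recommended course (12 weeks varenicline, 7 weeks bupropion,
   8 weeks NRT).
3. *Adherence* — the Medicines Possession Ratio was at least 80%.

All thresholds are closed: a course exactly at a boundary passes.  The
criteria form a conjunction, so the reclassification decision does not
depend on evaluation order; the order (timing, duration, adherence)
only fixes which criterion is attributed as the first failure in the
flow counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .exposure import TherapyCourse, exposed_during_pregnancy
from .records import PregnancyEpisode, TherapySpec
from .smoking import RecordedStatus

MPR_THRESHOLD = 80.0

DEFAULT_ORDER = ("timing", "duration", "mpr")


@dataclass(frozen=True)
class ClassificationResult:
    """Final smoking classification for one pregnancy.

    Criterion fields are ``None`` (not applicable) unless the pregnancy
    was exposed with no recorded smoking; ``failing_criterion`` is the
    first failed criterion in evaluation order, or ``"none"``.
    """

    pregnancy_id: str
    exposed: bool
    recorded_smoking: bool
    c1_timing: Optional[bool]
    c2_duration: Optional[bool]
    c3_mpr: Optional[bool]
    final_smoking: bool
    reclassified: bool
    failing_criterion: str
    all_missing: bool = False


def _index_spec(course: TherapyCourse, catalog: dict[str, TherapySpec]) -> TherapySpec:
    try:
        return catalog[course.index_supply.atc_code]
    except KeyError as exc:
        raise KeyError(
            f"index supply ATC {course.index_supply.atc_code!r} not in catalog"
        ) from exc


def criterion_timing(
    course: TherapyCourse,
    episode: PregnancyEpisode,
    catalog: dict[str, TherapySpec],
) -> bool:
    """Index supply at least the therapy lead time before conception."""
    spec = _index_spec(course, catalog)
    days_before = (episode.conception_date - course.index_supply.supply_date).days
    return days_before >= spec.lead_time_days


def criterion_duration(course: TherapyCourse, catalog: dict[str, TherapySpec]) -> bool:
    """Total days of supply reach the minimum recommended course."""
    spec = _index_spec(course, catalog)
    return course.total_days_supplied >= spec.min_course_days


def criterion_mpr(course: TherapyCourse) -> bool:
    """Medicines Possession Ratio at least 80%."""
    return course.mpr >= MPR_THRESHOLD


def classify(
    episode: PregnancyEpisode,
    course: Optional[TherapyCourse],
    recorded: RecordedStatus,
    catalog: dict[str, TherapySpec],
    order: Sequence[str] = DEFAULT_ORDER,
) -> ClassificationResult:
    """Classify one pregnancy.

    Unexposed pregnancies (no qualifying course, or a course whose
    coverage never extends past conception) keep their recorded status.
    Exposed pregnancies with recorded smoking are final smokers without
    entering the cascade.  Exposed pregnancies with no smoking record
    enter the cascade and are reclassified as smoking unless all three
    criteria pass.
    """
    exposed = course is not None and exposed_during_pregnancy(episode, course)
    rec = recorded.recorded_smoking
    if not exposed:
        return ClassificationResult(
            pregnancy_id=episode.pregnancy_id,
            exposed=False,
            recorded_smoking=rec,
            c1_timing=None,
            c2_duration=None,
            c3_mpr=None,
            final_smoking=rec,
            reclassified=False,
            failing_criterion="none",
            all_missing=recorded.all_missing,
        )
    if rec:
        return ClassificationResult(
            pregnancy_id=episode.pregnancy_id,
            exposed=True,
            recorded_smoking=True,
            c1_timing=None,
            c2_duration=None,
            c3_mpr=None,
            final_smoking=True,
            reclassified=False,
            failing_criterion="none",
            all_missing=recorded.all_missing,
        )
    if sorted(order) != sorted(DEFAULT_ORDER):
        raise ValueError(f"order must be a permutation of {DEFAULT_ORDER}, got {order}")
    outcomes = {
        "timing": criterion_timing(course, episode, catalog),
        "duration": criterion_duration(course, catalog),
        "mpr": criterion_mpr(course),
    }
    failing = next((c for c in order if not outcomes[c]), "none")
    reclassified = failing != "none"
    return ClassificationResult(
        pregnancy_id=episode.pregnancy_id,
        exposed=True,
        recorded_smoking=False,
        c1_timing=outcomes["timing"],
        c2_duration=outcomes["duration"],
        c3_mpr=outcomes["mpr"],
        final_smoking=reclassified,
        reclassified=reclassified,
        failing_criterion=failing,
        all_missing=recorded.all_missing,
    )


def cascade_counts(results: Iterable[ClassificationResult]) -> dict[str, int]:
    """Flow counts through the cascade, mirroring the sequential report.

    Counts satisfy ``n_exposed_unrecorded = fail_timing + fail_duration
    + fail_mpr + maintained`` and ``reclassified_total = fail_timing +
    fail_duration + fail_mpr`` (failures attributed to the first failing
    criterion in evaluation order).
    """
    counts = Counter(
        r.failing_criterion for r in results if r.exposed and not r.recorded_smoking
    )
    fail_timing = counts.get("timing", 0)
    fail_duration = counts.get("duration", 0)
    fail_mpr = counts.get("mpr", 0)
    maintained = counts.get("none", 0)
    return {
        "n_exposed_unrecorded": sum(counts.values()),
        "fail_timing": fail_timing,
        "fail_duration_given_timing_pass": fail_duration,
        "fail_mpr_given_both_pass": fail_mpr,
        "maintained": maintained,
        "reclassified_total": fail_timing + fail_duration + fail_mpr,
    }
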