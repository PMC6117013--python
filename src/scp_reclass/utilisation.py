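"""Lower- and upper-bound utilisation prevalence per therapy.

Utilisation of a therapy is the share of smoking pregnancies in which
that therapy was used during pregnancy.  The lower bound takes recorded
smokers only as the smoker set; the upper bound adds the pregnancies the
cascade reclassified as smoking.  Each therapy is measured only over the
listing era during which it was subsidised: episodes with a conception
date on or after the therapy's listing date and a delivery up to the
cohort end; "any" therapy uses the latest listing date so that all
therapies were available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from .exposure import TherapyCourse, exposed_during_pregnancy
from .records import DEFAULT_CATALOG, PregnancyEpisode, TherapySpec
from .reclassify import ClassificationResult

#: Last delivery date in the default measurement cohort.
DEFAULT_COHORT_END = date(2012, 12, 31)

THERAPIES = ("nrt", "bupropion", "varenicline", "any")


@dataclass(frozen=True)
class UtilisationEstimate:
    """One bound of the utilisation prevalence for one therapy era."""

    therapy: str
    era_start: date
    era_end: date
    bound: str  # "lower" | "upper"
    numerator: int
    denominator: int

    @property
    def prevalence(self) -> float:
        """Percentage, or NaN when the denominator is empty."""
        if self.denominator == 0:
            return math.nan
        return 100.0 * self.numerator / self.denominator


def _atc_for(therapy: str, catalog: Mapping[str, TherapySpec]) -> Optional[str]:
    if therapy == "any":
        return None
    for atc, spec in catalog.items():
        if spec.name == therapy or atc == therapy:
            return atc
    raise KeyError(f"therapy {therapy!r} not in catalog")


def era_start(therapy: str, catalog: Mapping[str, TherapySpec] = DEFAULT_CATALOG) -> date:
    """First conception date at which the therapy era opens."""
    if therapy == "any":
        return max(spec.listing_date for spec in catalog.values())
    return catalog[_atc_for(therapy, catalog)].listing_date


def era_filter(
    episodes: Iterable[PregnancyEpisode],
    therapy: str,
    catalog: Mapping[str, TherapySpec] = DEFAULT_CATALOG,
    cohort_end: date = DEFAULT_COHORT_END,
) -> list[PregnancyEpisode]:
    """Restrict episodes to the therapy's subsidy era (closed bounds)."""
    start = era_start(therapy, catalog)
    return [
        e
        for e in episodes
        if e.conception_date >= start and e.delivery_date <= cohort_end
    ]


def uses_therapy(
    episode: PregnancyEpisode,
    course: Optional[TherapyCourse],
    therapy: str,
    catalog: Mapping[str, TherapySpec] = DEFAULT_CATALOG,
) -> bool:
    """During-pregnancy use of a specific therapy (or any therapy).

    For a named therapy the course is restricted to that ATC's supplies
    and the exposure rule re-applied to the restriction, so a woman
    counts for NRT only if her NRT supplies themselves extend past
    conception.
    """
    if course is None:
        return False
    atc = _atc_for(therapy, catalog)
    if atc is None:
        return exposed_during_pregnancy(episode, course)
    sub = [s for s in course.supplies if s.atc_code == atc]
    if not sub:
        return False
    total = sum(s.days_covered for s in sub)
    conception = episode.conception_date
    if any(s.end_offset(conception) > 0 for s in sub):
        return True
    return (sub[0].supply_date - conception).days + total > 0


def estimate(
    episodes: Sequence[PregnancyEpisode],
    classifications: Mapping[str, ClassificationResult],
    courses: Mapping[str, Optional[TherapyCourse]],
    bound: str,
    therapy: str,
    catalog: Mapping[str, TherapySpec] = DEFAULT_CATALOG,
    cohort_end: date = DEFAULT_COHORT_END,
) -> UtilisationEstimate:
    """One utilisation bound for one therapy era.

    ``classifications`` and ``courses`` map pregnancy_id to the cascade
    result and pooled course.  The smoker set is recorded smokers for the
    lower bound, recorded-or-reclassified for the upper.
    """
    if bound not in ("lower", "upper"):
        raise ValueError(f"bound must be lower/upper, got {bound!r}")
    eligible = era_filter(episodes, therapy, catalog, cohort_end)
    numerator = 0
    denominator = 0
    for ep in eligible:
        res = classifications[ep.pregnancy_id]
        smoker = res.recorded_smoking if bound == "lower" else res.final_smoking
        if not smoker:
            continue
        denominator += 1
        if uses_therapy(ep, courses.get(ep.pregnancy_id), therapy, catalog):
            numerator += 1
    return UtilisationEstimate(
        therapy=therapy,
        era_start=era_start(therapy, catalog),
        era_end=cohort_end,
        bound=bound,
        numerator=numerator,
        denominator=denominator,
    )


def relative_increase(lower: float, upper: float) -> float:
    """Relative change from the lower- to the upper-bound prevalence.

    Reported as a percentage rounded to one decimal; NaN when the lower
    bound is zero or not finite.
    """
    if not math.isfinite(lower) or lower == 0:
        return math.nan
    return round(100.0 * (upper - lower) / lower, 1)
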