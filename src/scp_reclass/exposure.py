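"""Supply-course construction and during-pregnancy exposure ascertainment.

For each pregnancy episode, dispensing claims for smoking cessation
pharmacotherapy (SCP) within the window from 100 days before conception
to delivery are pooled into a single :class:`TherapyCourse`.  Days
covered by a supply are ``quantity / doses_per_day`` (twice daily for
varenicline and bupropion, once daily for NRT patches); fractional days
are carried exactly.  The course carries the index (earliest) supply,
the total days of supply, and the Medicines Possession Ratio

    MPR = 100 * total_days / ((final_supply_date + final_days) - index_date)

A pregnancy counts as exposed during pregnancy if either (i) any supply
date plus its days covered falls strictly after the conception date, or
(ii) the index supply date plus the total days supplied falls strictly
after the conception date.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional, Sequence

from .records import DispensingRecord, PregnancyEpisode, TherapySpec


class CatalogError(KeyError):
    """ATC code not present in the therapy catalog."""


@dataclass(frozen=True)
class SupplyEvent:
    """One in-window SCP supply, converted to days covered."""

    supply_date: date
    atc_code: str
    days_covered: float
    concession_status: str = "concessional"

    def end_offset(self, origin) -> float:
        """Supply end as a real-valued day offset from ``origin``."""
        return (self.supply_date - origin).days + self.days_covered


@dataclass(frozen=True)
class TherapyCourse:
    """All pooled SCP supplies for one pregnancy episode."""

    pregnancy_id: str
    supplies: tuple[SupplyEvent, ...]
    index_supply: SupplyEvent
    final_supply: SupplyEvent
    total_days_supplied: float
    mpr: float

    @property
    def n_supplies(self) -> int:
        return len(self.supplies)

    def atc_codes(self) -> set[str]:
        return {s.atc_code for s in self.supplies}


def days_covered(quantity: float, spec: TherapySpec) -> float:
    """Days covered by one supply: dispensed quantity over daily doses."""
    if quantity <= 0:
        raise ValueError(f"quantity must be > 0, got {quantity}")
    return quantity / spec.doses_per_day


def _mpr(supplies: Sequence[SupplyEvent], total_days: float) -> float:
    index = supplies[0]
    final = supplies[-1]
    denom = (final.supply_date - index.supply_date).days + final.days_covered
    if denom <= 0:
        raise ValueError("MPR denominator must be positive")
    return 100.0 * total_days / denom


def mpr(course: TherapyCourse) -> float:
    """Medicines Possession Ratio of a course, as a percentage.

    Uncapped: overlapping supplies can push the MPR above 100.
    """
    return _mpr(course.supplies, course.total_days_supplied)


def build_course(
    episode: PregnancyEpisode,
    dispensings: Iterable[DispensingRecord],
    catalog: dict[str, TherapySpec],
    atc: Optional[str] = None,
) -> Optional[TherapyCourse]:
    """Pool a woman's SCP supplies for one pregnancy into a course.

    Keeps only records whose ATC code is in ``catalog`` (optionally
    restricted to one code via ``atc``) and whose supply date lies in
    the closed window ``[lookback_start, delivery_date]``.  Returns
    ``None`` when no supply qualifies.  The index supply is the earliest;
    same-date ties break deterministically on (date, ATC code, input
    order).
    """
    events: list[tuple] = []
    for order, rec in enumerate(dispensings):
        if rec.atc_code not in catalog:
            continue
        if atc is not None and rec.atc_code != atc:
            continue
        if not episode.lookback_start <= rec.supply_date <= episode.delivery_date:
            continue
        event = SupplyEvent(
            supply_date=rec.supply_date,
            atc_code=rec.atc_code,
            days_covered=days_covered(rec.quantity, catalog[rec.atc_code]),
            concession_status=rec.concession_status,
        )
        events.append((rec.supply_date, rec.atc_code, order, event))
    if not events:
        return None
    events.sort(key=lambda t: t[:3])
    supplies = tuple(e[-1] for e in events)
    total = sum(s.days_covered for s in supplies)
    return TherapyCourse(
        pregnancy_id=episode.pregnancy_id,
        supplies=supplies,
        index_supply=supplies[0],
        final_supply=supplies[-1],
        total_days_supplied=total,
        mpr=_mpr(supplies, total),
    )


def exposed_during_pregnancy(episode: PregnancyEpisode, course: TherapyCourse) -> bool:
    """Decide during-pregnancy SCP exposure for a course.

    True iff any supply's coverage ends strictly after conception, or the
    index supply plus the total days supplied ends strictly after
    conception.  Ends falling exactly on the conception date do not
    count.
    """
    conception = episode.conception_date
    if any(s.end_offset(conception) > 0 for s in course.supplies):
        return True
    index_offset = (course.index_supply.supply_date - conception).days
    return index_offset + course.total_days_supplied > 0
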