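"""Recorded smoking status from perinatal items and delivery diagnoses.

A woman is recorded as smoking during pregnancy if any populated
smoking item on the perinatal record is positive, or the hospital
separation spanning the delivery carries the ICD-10-AM code Z72.0
(current tobacco use).  Negative and missing responses are pooled as
"smoking not reported" for classification, but an all-missing flag is
kept so audits can distinguish the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Optional

from .records import HospitalSeparation, PerinatalRecord, PregnancyEpisode

TOBACCO_USE_CODE = "Z720"  # Z72.0 after normalisation


def _normalise_icd(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class RecordedStatus:
    """Recorded-smoking outcome for one pregnancy, by source."""

    pregnancy_id: str
    perinatal_positive: bool
    hospital_positive: bool
    all_missing: bool

    @property
    def recorded_smoking(self) -> bool:
        return self.perinatal_positive or self.hospital_positive


def perinatal_smoking(p: PerinatalRecord) -> bool:
    """True iff any populated perinatal smoking item is positive."""
    return any(
        flag is True
        for flag in (p.smoked_any, p.smoked_first_half, p.smoked_second_half)
    )


def perinatal_all_missing(p: PerinatalRecord) -> bool:
    """True iff every smoking item on the record is missing."""
    return (
        p.smoked_any is None
        and p.smoked_first_half is None
        and p.smoked_second_half is None
    )


def delivery_separation(
    episode: PregnancyEpisode,
    seps: Iterable[HospitalSeparation],
    tolerance_days: int = 0,
) -> Optional[HospitalSeparation]:
    """Pick the hospital separation related to the delivery.

    The delivery separation is the one whose [admission, separation]
    interval contains the delivery date (optionally widened by
    ``tolerance_days`` on each side for transfer records).  Ties are
    broken by earliest admission, then earliest separation.  Returns
    ``None`` when no interval contains the delivery.
    """
    tol = timedelta(days=tolerance_days)
    candidates = [
        s
        for s in seps
        if s.admission_date - tol <= episode.delivery_date <= s.separation_date + tol
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda s: (s.admission_date, s.separation_date))


def hospital_smoking(sep: Optional[HospitalSeparation]) -> bool:
    """True iff the delivery separation carries a Z72.0 diagnosis.

    Exact-code match after period/whitespace normalisation; other child
    codes of Z72 do not match.
    """
    if sep is None:
        return False
    return any(_normalise_icd(c) == TOBACCO_USE_CODE for c in sep.diagnosis_codes)


def recorded_status(
    episode: PregnancyEpisode,
    perinatal: PerinatalRecord,
    seps: Iterable[HospitalSeparation],
    tolerance_days: int = 0,
) -> RecordedStatus:
    """Combine both sources into the recorded-smoking outcome."""
    sep = delivery_separation(episode, seps, tolerance_days=tolerance_days)
    hospital_positive = hospital_smoking(sep)
    # all_missing marks a non-smoking call resting on absent data rather
    # than negative responses: every perinatal item missing and no Z72.0.
    return RecordedStatus(
        pregnancy_id=episode.pregnancy_id,
        perinatal_positive=perinatal_smoking(perinatal),
        hospital_positive=hospital_positive,
        all_missing=perinatal_all_missing(perinatal) and not hospital_positive,
    )
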