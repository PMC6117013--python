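"""Synthetic linked perinatal/hospital/dispensing data with ground truth.

The generator emulates the statistical structure of linked state
administrative data: one delivery record per pregnancy with maternal
smoking items (in the era-appropriate reporting dialect), a hospital
separation spanning every delivery (with Z72.0 injected when smoking is
recorded through the hospital route), and subsidised dispensing claims
for smoking cessation pharmacotherapy.

Generation is scenario-based rather than mechanistic: each exposed
pregnancy is assigned one supply-pattern scenario constructed to land on
a known side of the cascade's criteria —

* ``quitter_full_course`` — true pre-conception quitter; index supply at
  least the lead time before conception, consecutive supplies reaching
  the minimum course (MPR 100).  Passes all three criteria.
* ``continuing_late_start`` — index supply inside the lead-time window
  (or after conception).  Fails timing.
* ``continuing_short_course`` — timely index but total days below the
  minimum course.  Fails duration.
* ``continuing_low_mpr`` — timely index and full course, but a gap
  between supplies pushing the MPR below 80%.  Fails adherence.

True smokers are recorded as smoking with a probability given by a
logistic model on demographics; negative coefficients on married,
private-hospital, general-beneficiary, age 30+ and top-SEIFA status
reproduce the under-reporting gradients described in the validation
literature.  A truth table with per-pregnancy labels is emitted for
evaluation only and is never read by the classification pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    DEFAULT_CATALOG,
    DispensingRecord,
    HospitalSeparation,
    PerinatalRecord,
    TherapySpec,
    write_records,
)
from .reclassify import ClassificationResult

SCENARIOS = (
    "quitter_full_course",
    "continuing_late_start",
    "continuing_short_course",
    "continuing_low_mpr",
)


class ConfigError(ValueError):
    """Generator configuration is invalid or infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults target the composition observed in the motivating cohort:
    ~14% smoking prevalence, 5% of pregnancies exposed to cessation
    pharmacotherapy, exposed-arm scenario shares of roughly 13% true
    quitters / 58% late starters / 23% short courses / 6% low adherence,
    and a recorded-smoking probability averaging ~0.62 among continuing
    smokers with under-reporting concentrated in married, private,
    general-beneficiary, older and high-SES women.
    """

    n_women: int = 5000
    seed: int = 42
    delivery_start: date = date(2009, 1, 1)
    delivery_end: date = date(2012, 12, 31)
    gestation_mean: float = 39.0
    gestation_sd: float = 2.0
    gestation_min: int = 20
    gestation_max: int = 43
    smoking_prevalence: float = 0.14
    # demographic marginals
    p_age_ge_30: float = 0.45
    p_married: float = 0.60
    seifa_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    p_private: float = 0.10
    p_general: float = 0.35
    p_nsw: float = 0.70
    # reporting model: P(recorded | true smoker) = sigmoid(intercept + x'coef)
    reporting_intercept: float = 1.65
    reporting_coefs: dict = field(
        default_factory=lambda: {
            "age_ge_30": -0.24,
            "married": -0.72,
            "private_hospital": -0.99,
            "general_beneficiary": -1.04,
            "seifa_q1": -0.75,
        }
    )
    p_perinatal_route: float = 0.80
    p_missing_items: float = 0.005
    # exposure model
    p_exposed: float = 0.05
    scenario_mixture: dict = field(
        default_factory=lambda: {
            "quitter_full_course": 0.130,
            "continuing_late_start": 0.575,
            "continuing_short_course": 0.231,
            "continuing_low_mpr": 0.064,
        }
    )
    # nuisance records
    p_extra_dispensing: float = 0.05
    p_extra_separation: float = 0.30

    def validate(self, catalog: dict[str, TherapySpec] = DEFAULT_CATALOG) -> None:
        probs = [
            self.smoking_prevalence,
            self.p_age_ge_30,
            self.p_married,
            self.p_private,
            self.p_general,
            self.p_nsw,
            self.p_perinatal_route,
            self.p_missing_items,
            self.p_exposed,
            self.p_extra_dispensing,
            self.p_extra_separation,
            *self.seifa_probs,
            *self.scenario_mixture.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if len(self.seifa_probs) != 5 or not math.isclose(sum(self.seifa_probs), 1.0):
            raise ConfigError("seifa_probs must be 5 probabilities summing to 1")
        if set(self.scenario_mixture) != set(SCENARIOS):
            raise ConfigError(f"scenario_mixture keys must be {SCENARIOS}")
        if not math.isclose(sum(self.scenario_mixture.values()), 1.0):
            raise ConfigError("scenario_mixture must sum to 1")
        if self.n_women <= 0:
            raise ConfigError("n_women must be positive")
        if self.delivery_start >= self.delivery_end:
            raise ConfigError("delivery date range is empty")
        if not 20 <= self.gestation_min <= self.gestation_max <= 45:
            raise ConfigError("gestation truncation must lie within [20, 45]")
        for spec in catalog.values():
            # a full quitter course must fit: lead time before conception,
            # index inside the 100-day lookback, coverage past conception
            if spec.lead_time_days > spec.min_course_days - 7:
                raise ConfigError(
                    f"{spec.name}: course too short to separate quitters"
                )
            if spec.min_course_days - 7 > 100:
                raise ConfigError(f"{spec.name}: course exceeds lookback window")


@dataclass
class SyntheticCohort:
    """Generated record streams plus the evaluation-only truth table."""

    perinatal: list[PerinatalRecord]
    hospital: list[HospitalSeparation]
    dispensing: list[DispensingRecord]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "perinatal": out / "perinatal.csv",
            "hospital": out / "hospital.csv",
            "dispensing": out / "dispensing.csv",
            "truth": out / "truth.csv",
        }
        write_records(paths["perinatal"], self.perinatal, "perinatal")
        write_records(paths["hospital"], self.hospital, "hospital")
        write_records(paths["dispensing"], self.dispensing, "dispensing")
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _half_dialect(state: str, delivery: date) -> bool:
    # perinatal collections moved from an any-time item to half-of-
    # pregnancy items in 2010 (WA) and 2011 (NSW)
    return delivery.year >= (2010 if state == "WA" else 2011)


def _chunks(total: int, size: int = 28) -> list[int]:
    out = [size] * (total // size)
    if total % size:
        out.append(total % size)
    return out


def _supply_pattern(
    rng: np.random.Generator, scenario: str, spec: TherapySpec
) -> list[tuple[int, int]]:
    """Supply pattern as (days_before_conception, days_covered) pairs."""
    lead, course = spec.lead_time_days, spec.min_course_days
    if scenario == "quitter_full_course":
        offset = int(rng.integers(lead, course - 7 + 1))
        pattern = []
        pos = offset
        for chunk in _chunks(course):
            pattern.append((pos, chunk))
            pos -= chunk
        return pattern
    if scenario == "continuing_late_start":
        offset = int(rng.integers(-60, lead))  # < lead: fails timing
        return [(offset, 28)]
    if scenario == "continuing_short_course":
        offset = int(rng.integers(lead, lead + 15))
        return [(offset, offset + 14)]  # < minimum course for all therapies
    if scenario == "continuing_low_mpr":
        offset = int(rng.integers(lead, lead + 8))
        s1 = math.ceil(course / 2)
        s2 = course - s1
        gap = math.ceil(0.35 * course) + int(rng.integers(0, 7))
        return [(offset, s1), (offset - s1 - gap, s2)]
    raise ConfigError(f"unknown scenario {scenario!r}")


def generate(
    config: GeneratorConfig,
    catalog: dict[str, TherapySpec] = DEFAULT_CATALOG,
) -> SyntheticCohort:
    """Generate one linked synthetic cohort, deterministic given the seed."""
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    atcs = sorted(catalog)
    scenario_names = list(SCENARIOS)
    scenario_probs = [config.scenario_mixture[s] for s in scenario_names]

    perinatal: list[PerinatalRecord] = []
    hospital: list[HospitalSeparation] = []
    dispensing: list[DispensingRecord] = []
    truth_rows: list[dict] = []

    span_days = (config.delivery_end - config.delivery_start).days

    for i in range(config.n_women):
        woman_id = f"W{i:06d}"
        pregnancy_id = f"P{i:06d}"
        state = "NSW" if rng.random() < config.p_nsw else "WA"
        delivery = config.delivery_start + timedelta(days=int(rng.integers(0, span_days + 1)))
        gestation = int(
            np.clip(
                round(rng.normal(config.gestation_mean, config.gestation_sd)),
                config.gestation_min,
                config.gestation_max,
            )
        )
        conception = delivery - timedelta(days=7 * gestation - 14)

        age_ge_30 = rng.random() < config.p_age_ge_30
        age = int(rng.integers(30, 43)) if age_ge_30 else int(rng.integers(18, 30))
        married = rng.random() < config.p_married
        seifa = int(rng.choice(5, p=config.seifa_probs)) + 1
        private = rng.random() < config.p_private
        general = rng.random() < config.p_general

        if rng.random() < config.p_exposed:
            scenario = str(rng.choice(scenario_names, p=scenario_probs))
        else:
            scenario = "unexposed"
        if scenario == "unexposed":
            true_smoker = rng.random() < config.smoking_prevalence
            true_quit = False
        elif scenario == "quitter_full_course":
            true_smoker = False
            true_quit = True
        else:
            true_smoker = True
            true_quit = False

        # --- recorded smoking status -----------------------------------
        recorded = False
        if true_smoker:
            x = (
                config.reporting_intercept
                + config.reporting_coefs.get("age_ge_30", 0.0) * age_ge_30
                + config.reporting_coefs.get("married", 0.0) * married
                + config.reporting_coefs.get("private_hospital", 0.0) * private
                + config.reporting_coefs.get("general_beneficiary", 0.0) * general
                + config.reporting_coefs.get("seifa_q1", 0.0) * (seifa == 1)
            )
            recorded = rng.random() < 1.0 / (1.0 + math.exp(-x))
        missing_items = rng.random() < config.p_missing_items
        perinatal_route = recorded and rng.random() < config.p_perinatal_route
        if perinatal_route and missing_items:
            perinatal_route = False  # recording falls to the hospital code
        hospital_route = recorded and not perinatal_route

        half = _half_dialect(state, delivery)
        if missing_items:
            smoked_any = first = second = None
        elif half:
            smoked_any = None
            first = perinatal_route
            second = perinatal_route and rng.random() < 0.7
        else:
            smoked_any = perinatal_route
            first = second = None

        perinatal.append(
            PerinatalRecord(
                pregnancy_id=pregnancy_id,
                woman_id=woman_id,
                delivery_date=delivery,
                gestation_weeks=gestation,
                smoked_any=smoked_any,
                smoked_first_half=first,
                smoked_second_half=second,
                maternal_age=age,
                marital_status="married" if married else "not_married",
                seifa_quintile=seifa,
                hospital_type="private" if private else "public",
                state=state,
            )
        )

        # --- hospital separations --------------------------------------
        codes = ["O80"]
        if hospital_route:
            codes.append("Z72.0")
        admission = delivery - timedelta(days=int(rng.integers(0, 3)))
        separation = delivery + timedelta(days=int(rng.integers(1, 5)))
        hospital.append(
            HospitalSeparation(woman_id, admission, separation, tuple(codes))
        )
        if rng.random() < config.p_extra_separation:
            adm = delivery - timedelta(days=int(rng.integers(40, 90)))
            hospital.append(
                HospitalSeparation(woman_id, adm, adm + timedelta(days=2), ("R10.4",))
            )

        # --- dispensing claims -----------------------------------------
        concession = "general" if general else "concessional"
        if scenario != "unexposed":
            atc = str(rng.choice(atcs))
            spec = catalog[atc]
            for days_before, days in _supply_pattern(rng, scenario, spec):
                dispensing.append(
                    DispensingRecord(
                        woman_id=woman_id,
                        supply_date=conception - timedelta(days=days_before),
                        atc_code=atc,
                        quantity=days * spec.doses_per_day,
                        concession_status=concession,
                    )
                )
        else:
            atc = ""
        if rng.random() < config.p_extra_dispensing:
            dispensing.append(
                DispensingRecord(
                    woman_id=woman_id,
                    supply_date=delivery - timedelta(days=int(rng.integers(0, 200))),
                    atc_code="J01CA04",  # non-SCP claim, must be ignored
                    quantity=20,
                    concession_status=concession,
                )
            )

        truth_rows.append(
            {
                "pregnancy_id": pregnancy_id,
                "woman_id": woman_id,
                "scenario": scenario,
                "true_smoker": true_smoker,
                "true_quit_preconception": true_quit,
                "exposed": scenario != "unexposed",
                "recorded": recorded,
                "atc_code": atc,
            }
        )

    return SyntheticCohort(
        perinatal=perinatal,
        hospital=hospital,
        dispensing=dispensing,
        truth=pd.DataFrame(truth_rows),
    )


def evaluate_against_truth(
    classifications: Sequence[ClassificationResult], truth: pd.DataFrame
) -> dict:
    """Confusion summary of final smoking status against generator truth.

    Reports sensitivity, specificity and PPV of ``final_smoking`` vs
    ``true_smoker`` overall and within the exposed-unrecorded stratum
    (the only stratum the cascade acts on).  Raises if the id sets do
    not align.
    """
    by_id = {r.pregnancy_id: r for r in classifications}
    if set(by_id) != set(truth["pregnancy_id"]):
        raise ValueError("classification and truth pregnancy ids do not align")

    def confusion(rows: pd.DataFrame) -> dict:
        tp = fp = tn = fn = 0
        for _, row in rows.iterrows():
            pred = by_id[row["pregnancy_id"]].final_smoking
            if row["true_smoker"]:
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
        return {
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
            "specificity": tn / (tn + fp) if tn + fp else math.nan,
            "ppv": tp / (tp + fp) if tp + fp else math.nan,
        }

    stratum_ids = [
        pid
        for pid, r in by_id.items()
        if r.exposed and not r.recorded_smoking
    ]
    return {
        "overall": confusion(truth),
        "exposed_unrecorded": confusion(
            truth[truth["pregnancy_id"].isin(stratum_ids)]
        ),
    }
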