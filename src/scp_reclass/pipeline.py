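"""End-to-end orchestration: derive, ascertain, classify, estimate, report.

``classify_cohort`` is the in-memory core used by the command line, the
tests and the examples; ``run_pipeline`` wraps it with CSV input/output
and writes the full report bundle (per-stage CSVs, ``cascade.json`` and
``report.json``).  All outputs are deterministic functions of the inputs
and options.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import exposure, records, reclassify, smoking, utilisation, validity
from .records import (
    DEFAULT_CATALOG,
    DispensingRecord,
    HospitalSeparation,
    PerinatalRecord,
    TherapySpec,
)

log = logging.getLogger("scp_reclass")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and options for one pipeline run."""

    perinatal_path: Path
    hospital_path: Path
    dispensing_path: Path
    catalog_path: Optional[Path] = None
    out_dir: Optional[Path] = None
    confidence: float = 0.95
    continuity: bool = False
    separation_tolerance_days: int = 0
    criterion_order: tuple[str, str, str] = reclassify.DEFAULT_ORDER
    cohort_end: date = utilisation.DEFAULT_COHORT_END

    def validate(self) -> None:
        for p in (self.perinatal_path, self.hospital_path, self.dispensing_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.catalog_path is not None and not Path(self.catalog_path).exists():
            raise FileNotFoundError(self.catalog_path)
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if sorted(self.criterion_order) != sorted(reclassify.DEFAULT_ORDER):
            raise ValueError("criterion_order must permute (timing, duration, mpr)")


@dataclass
class CohortClassification:
    """Classified cohort: one entry per pregnancy episode."""

    episodes: dict[str, records.PregnancyEpisode]
    courses: dict[str, Optional[exposure.TherapyCourse]]
    recorded: dict[str, smoking.RecordedStatus]
    results: list[reclassify.ClassificationResult]

    @property
    def cascade(self) -> dict[str, int]:
        return reclassify.cascade_counts(self.results)


def classify_cohort(
    perinatal: Sequence[PerinatalRecord],
    hospital: Sequence[HospitalSeparation],
    dispensing: Sequence[DispensingRecord],
    catalog: dict[str, TherapySpec] = DEFAULT_CATALOG,
    separation_tolerance_days: int = 0,
    criterion_order: Sequence[str] = reclassify.DEFAULT_ORDER,
) -> CohortClassification:
    """Run derive → exposure → recorded status → cascade for a cohort."""
    seps_by_woman: dict[str, list[HospitalSeparation]] = defaultdict(list)
    for sep in hospital:
        seps_by_woman[sep.woman_id].append(sep)
    disp_by_woman: dict[str, list[DispensingRecord]] = defaultdict(list)
    for d in dispensing:
        disp_by_woman[d.woman_id].append(d)

    episodes: dict[str, records.PregnancyEpisode] = {}
    courses: dict[str, Optional[exposure.TherapyCourse]] = {}
    recorded: dict[str, smoking.RecordedStatus] = {}
    results: list[reclassify.ClassificationResult] = []
    for p in perinatal:
        ep = records.derive_episode(p)
        episodes[ep.pregnancy_id] = ep
        course = exposure.build_course(ep, disp_by_woman.get(ep.woman_id, ()), catalog)
        courses[ep.pregnancy_id] = course
        status = smoking.recorded_status(
            ep,
            p,
            seps_by_woman.get(ep.woman_id, ()),
            tolerance_days=separation_tolerance_days,
        )
        recorded[ep.pregnancy_id] = status
        result = reclassify.classify(ep, course, status, catalog, order=criterion_order)
        results.append(result)
        if result.exposed and not result.recorded_smoking:
            log.debug(
                "pregnancy %s: timing=%s duration=%s mpr=%s -> %s",
                ep.pregnancy_id,
                result.c1_timing,
                result.c2_duration,
                result.c3_mpr,
                "reclassified" if result.reclassified else "maintained",
            )
    return CohortClassification(episodes, courses, recorded, results)


def utilisation_table(
    cohort: CohortClassification,
    catalog: dict[str, TherapySpec] = DEFAULT_CATALOG,
    cohort_end: date = utilisation.DEFAULT_COHORT_END,
) -> list[utilisation.UtilisationEstimate]:
    """Lower and upper utilisation bounds for every therapy era."""
    by_id = {r.pregnancy_id: r for r in cohort.results}
    episodes = list(cohort.episodes.values())
    out = []
    for therapy in utilisation.THERAPIES:
        for bound in ("lower", "upper"):
            out.append(
                utilisation.estimate(
                    episodes, by_id, cohort.courses, bound, therapy, catalog, cohort_end
                )
            )
    return out


def validity_report(
    cohort: CohortClassification,
    confidence: float = 0.95,
    continuity: bool = False,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Factor tables with crude (and optionally adjusted) odds ratios."""
    tables = validity.build_tables(cohort.results, cohort.episodes, cohort.courses)
    rows = []
    for ft in tables:
        t = ft.table
        try:
            orr = validity.crude_or(t, confidence=confidence, continuity=continuity)
            or_value, lo, hi = orr.rounded(2)
        except ValueError:
            or_value = lo = hi = math.nan
        rows.append(
            {
                "factor": ft.factor,
                "level": ft.level,
                "n_reclassified_pos": t.a,
                "n_reclassified_neg": t.b,
                "n_recorded_pos": t.c,
                "n_recorded_neg": t.d,
                "crude_or": or_value,
                "ci_low": lo,
                "ci_high": hi,
                "n_excluded_missing": ft.n_excluded_missing,
            }
        )
    table = pd.DataFrame(rows)
    if adjusted:
        fit = _adjusted_fit(cohort, confidence)
        if fit is not None and fit.converged:
            adj = {
                row["term"]: (row["or"], row["ci_low"], row["ci_high"])
                for _, row in fit.table.iterrows()
            }
            table["adjusted_or"] = [
                round(adj[f][0], 2) if f in adj else math.nan for f in table["factor"]
            ]
        else:
            table["adjusted_or"] = math.nan
    return table


def _adjusted_fit(cohort: CohortClassification, confidence: float):
    """Joint logistic fit over the binary factors, where estimable."""
    rows, outcome = [], []
    for r in cohort.results:
        if not (r.exposed and r.final_smoking):
            continue
        ep = cohort.episodes[r.pregnancy_id]
        course = cohort.courses[r.pregnancy_id]
        if course is None:
            continue
        rows.append(
            {
                "age_ge_30": ep.maternal_age >= 30,
                "married": ep.marital_status == "married",
                "private_hospital": ep.hospital_type == "private",
                "general_beneficiary": course.index_supply.concession_status == "general",
            }
        )
        outcome.append(int(r.reclassified))
    if len(rows) < 10 or len(set(outcome)) < 2:
        return None
    design = pd.DataFrame(rows)
    return validity.adjusted_logit(design, outcome, confidence=confidence)


@dataclass
class PipelineResult:
    cohort: CohortClassification
    cascade: dict[str, int]
    utilisation: list[utilisation.UtilisationEstimate]
    validity: pd.DataFrame
    report: dict


def _utilisation_frame(estimates: list[utilisation.UtilisationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "therapy": e.therapy,
            "era_start": e.era_start.isoformat(),
            "era_end": e.era_end.isoformat(),
            "bound": e.bound,
            "numerator": e.numerator,
            "denominator": e.denominator,
            "prevalence_pct": round(e.prevalence, 1) if math.isfinite(e.prevalence) else math.nan,
        }
        for e in estimates
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; write the report bundle if requested."""
    config.validate()
    catalog = (
        records.load_catalog(config.catalog_path)
        if config.catalog_path
        else DEFAULT_CATALOG
    )
    try:
        perinatal, _ = records.read_records(config.perinatal_path, "perinatal")
        hospital, _ = records.read_records(config.hospital_path, "hospital")
        dispensing, _ = records.read_records(config.dispensing_path, "dispensing")
    except (records.SchemaError, records.InvariantError) as exc:
        raise RuntimeError(f"stage=read: {exc}") from exc

    cohort = classify_cohort(
        perinatal,
        hospital,
        dispensing,
        catalog,
        separation_tolerance_days=config.separation_tolerance_days,
        criterion_order=tuple(config.criterion_order),
    )
    cascade = cohort.cascade
    estimates = utilisation_table(cohort, catalog, config.cohort_end)
    validity_df = validity_report(
        cohort, confidence=config.confidence, continuity=config.continuity
    )

    rel = {}
    for therapy in utilisation.THERAPIES:
        pair = {e.bound: e.prevalence for e in estimates if e.therapy == therapy}
        rel[therapy] = utilisation.relative_increase(pair["lower"], pair["upper"])

    report = {
        "n_pregnancies": len(cohort.episodes),
        "n_exposed": sum(r.exposed for r in cohort.results),
        "n_recorded_smoking_among_exposed": sum(
            r.exposed and r.recorded_smoking for r in cohort.results
        ),
        "cascade": cascade,
        "utilisation": [
            {
                "therapy": e.therapy,
                "bound": e.bound,
                "numerator": e.numerator,
                "denominator": e.denominator,
                "prevalence_pct": round(e.prevalence, 1)
                if math.isfinite(e.prevalence)
                else None,
            }
            for e in estimates
        ],
        "relative_increase_pct": {
            k: (v if math.isfinite(v) else None) for k, v in rel.items()
        },
        "face_validity": validity_df.where(pd.notna(validity_df), None).to_dict(
            orient="records"
        ),
        "note": (
            "upper-bound prevalence may overestimate: smokers without claims "
            "are absent from the reclassified denominator"
        ),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.write_records(
            out / "episodes.csv", list(cohort.episodes.values()), "episodes"
        )
        _courses_frame(cohort).to_csv(out / "courses.csv", index=False)
        _recorded_frame(cohort).to_csv(out / "recorded_status.csv", index=False)
        _classification_frame(cohort).to_csv(out / "classification.csv", index=False)
        with open(out / "cascade.json", "w") as fh:
            json.dump(cascade, fh, indent=2, sort_keys=True)
        _utilisation_frame(estimates).to_csv(out / "utilisation.csv", index=False)
        validity_df.to_csv(out / "face_validity.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    return PipelineResult(cohort, cascade, estimates, validity_df, report)


def _courses_frame(cohort: CohortClassification) -> pd.DataFrame:
    rows = []
    by_id = {r.pregnancy_id: r for r in cohort.results}
    for pid, course in sorted(cohort.courses.items()):
        if course is None:
            continue
        rows.append(
            {
                "pregnancy_id": pid,
                "index_date": course.index_supply.supply_date.isoformat(),
                "index_atc": course.index_supply.atc_code,
                "n_supplies": course.n_supplies,
                "total_days": course.total_days_supplied,
                "mpr": round(course.mpr, 2),
                "exposed": by_id[pid].exposed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pregnancy_id",
            "index_date",
            "index_atc",
            "n_supplies",
            "total_days",
            "mpr",
            "exposed",
        ],
    )


def _recorded_frame(cohort: CohortClassification) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pregnancy_id": s.pregnancy_id,
            "perinatal_positive": s.perinatal_positive,
            "hospital_positive": s.hospital_positive,
            "recorded_smoking": s.recorded_smoking,
            "all_missing": s.all_missing,
        }
        for s in (cohort.recorded[p] for p in sorted(cohort.recorded))
    )


def _classification_frame(cohort: CohortClassification) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pregnancy_id": r.pregnancy_id,
            "exposed": r.exposed,
            "recorded_smoking": r.recorded_smoking,
            "c1_timing": r.c1_timing,
            "c2_duration": r.c2_duration,
            "c3_mpr": r.c3_mpr,
            "final_smoking": r.final_smoking,
            "reclassified": r.reclassified,
            "failing_criterion": r.failing_criterion,
            "all_missing": r.all_missing,
        }
        for r in sorted(cohort.results, key=lambda r: r.pregnancy_id)
    )
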