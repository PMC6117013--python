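"""Face-validity analysis: factors associated with reclassification.

Under-reporting of smoking in pregnancy is known to be more common among
older (30+), married, higher-socioeconomic-status women and private
hospital deliveries.  If the cascade has face validity, those factors
should be over-represented among women it reclassifies as smoking,
relative to women whose smoking was recorded.  This module builds the
2x2 tables (reclassified vs recorded, factor present vs absent), their
crude odds ratios with Wald confidence intervals, and an optional
adjusted logistic model over all factors jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import TherapyCourse
from .records import PregnancyEpisode
from .reclassify import ClassificationResult

FACTORS = ("age_ge_30", "married", "private_hospital", "general_beneficiary", "seifa")


@dataclass(frozen=True)
class TwoByTwo:
    """Counts for one factor: reclassified (a, b) vs recorded (c, d).

    a and c hold the factor-present cells, b and d the factor-absent
    (reference) cells.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.value, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def crude_or(
    t: TwoByTwo, confidence: float = 0.95, continuity: bool = False
) -> OddsRatio:
    """Crude odds ratio (a*d)/(b*c) with a Wald log-OR interval.

    With ``continuity=True`` the Haldane–Anscombe correction adds 0.5 to
    every cell when any cell is zero; otherwise a zero cell raises.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError("zero cell; enable continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = stats.norm.ppf(0.5 + confidence / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(
        value=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
    )


@dataclass(frozen=True)
class FactorTable:
    """One factor level's 2x2 table within the final-smoker cohort."""

    factor: str
    level: str
    table: TwoByTwo
    n_excluded_missing: int = 0


def _factor_value(
    ep: PregnancyEpisode, course: Optional[TherapyCourse], factor: str
) -> Optional[bool]:
    if factor == "age_ge_30":
        return ep.maternal_age >= 30
    if factor == "married":
        return ep.marital_status == "married"
    if factor == "private_hospital":
        return ep.hospital_type == "private"
    if factor == "general_beneficiary":
        # beneficiary status comes from the dispensing claim itself
        if course is None:
            return None
        return course.index_supply.concession_status == "general"
    raise KeyError(f"unknown factor {factor!r}")


def build_tables(
    classifications: Sequence[ClassificationResult],
    episodes: Mapping[str, PregnancyEpisode],
    courses: Mapping[str, Optional[TherapyCourse]],
) -> list[FactorTable]:
    """2x2 tables of reclassified vs recorded smokers, per factor.

    Restricted to SCP-exposed pregnancies with final smoking status,
    split into the recorded-smoking arm and the reclassified arm.  One
    table per binary factor; one table per SEIFA quintile 1–4 against
    quintile 5 as reference.  Episodes missing a factor's value are
    excluded from that factor's table only.
    """
    cohort = [r for r in classifications if r.exposed and r.final_smoking]
    tables: list[FactorTable] = []
    for factor in ("age_ge_30", "married", "private_hospital", "general_beneficiary"):
        a = b = c = d = missing = 0
        for r in cohort:
            value = _factor_value(episodes[r.pregnancy_id], courses.get(r.pregnancy_id), factor)
            if value is None:
                missing += 1
                continue
            if r.reclassified:
                a, b = (a + 1, b) if value else (a, b + 1)
            else:
                c, d = (c + 1, d) if value else (c, d + 1)
        tables.append(FactorTable(factor, "yes", TwoByTwo(a, b, c, d), missing))
    # SEIFA quintiles vs quintile 5 reference
    seifa_counts: dict[tuple[int, bool], int] = {}
    missing = 0
    for r in cohort:
        q = episodes[r.pregnancy_id].seifa_quintile
        if q is None:
            missing += 1
            continue
        key = (q, r.reclassified)
        seifa_counts[key] = seifa_counts.get(key, 0) + 1
    ref_re = seifa_counts.get((5, True), 0)
    ref_rec = seifa_counts.get((5, False), 0)
    for q in (1, 2, 3, 4):
        tables.append(
            FactorTable(
                "seifa",
                f"q{q}_vs_q5",
                TwoByTwo(
                    seifa_counts.get((q, True), 0),
                    ref_re,
                    seifa_counts.get((q, False), 0),
                    ref_rec,
                ),
                missing,
            )
        )
    return tables


@dataclass(frozen=True)
class LogitFit:
    """Adjusted logistic model fit (reclassified ~ factors)."""

    converged: bool
    table: Optional[pd.DataFrame]  # term, coef, or, ci_low, ci_high, se
    condition_number: Optional[float]
    message: str = ""


def adjusted_logit(
    design: pd.DataFrame,
    outcome: Sequence[int] | Sequence[bool],
    confidence: float = 0.95,
) -> LogitFit:
    """Maximum-likelihood logistic fit of the reclassified flag.

    ``design`` holds one column per factor indicator (no intercept; one
    is added).  Returns exponentiated coefficients with Wald intervals
    and the design condition number as a collinearity report.  On
    separation or non-convergence no estimates are emitted.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    cond = float(np.linalg.cond(np.asarray(X)))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises here
        return LogitFit(False, None, cond, message=str(exc))
    if not fit.mle_retvals.get("converged", False):
        return LogitFit(False, None, cond, message="did not converge")
    z = stats.norm.ppf(0.5 + confidence / 2)
    rows = []
    for term, coef, se in zip(X.columns, fit.params, fit.bse):
        rows.append(
            {
                "term": term,
                "coef": coef,
                "se": se,
                "or": math.exp(coef) if term != "const" else math.nan,
                "ci_low": math.exp(coef - z * se) if term != "const" else math.nan,
                "ci_high": math.exp(coef + z * se) if term != "const" else math.nan,
            }
        )
    return LogitFit(True, pd.DataFrame(rows), cond)
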