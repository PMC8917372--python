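"""Analytic-sample construction and labor-status classification.

Reproduces the study's sample rules on any schema-conforming microdata:
keep first-visit households only (removes quarterly redundancy of the
rotating panel), keep economically active persons whose occupation code is
in the nurse catalogue, and drop records with incomplete information on the
variables of interest. Every stage is counted in a :class:`SampleAudit`.

Labor status partitions the economically active nurses into three mutually
exclusive categories:

* ``unemployed`` — not working for pay though available and seeking;
* ``underemployed`` — working, but outside the health sector (the
  professional-market sense of underemployment: trained nurses absorbed by
  other markets);
* ``employed_health`` — working in the health sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import schema as sch
from .exceptions import ConfigurationError, DomainError

LABOR_STATUSES = ("unemployed", "underemployed", "employed_health")


@dataclass(frozen=True)
class PeriodBin:
    """One federal-administration period; the six bins partition 2005-2019."""

    label: str
    start: int
    end: int

    def __contains__(self, year: int) -> bool:
        return self.start <= year <= self.end


PERIOD_BINS = (
    PeriodBin("2005-2006", 2005, 2006),
    PeriodBin("2007-2009", 2007, 2009),
    PeriodBin("2010-2012", 2010, 2012),
    PeriodBin("2013-2015", 2013, 2015),
    PeriodBin("2016-2018", 2016, 2018),
    PeriodBin("2019", 2019, 2019),
)

PERIOD_LABELS = tuple(b.label for b in PERIOD_BINS)

#: Covariates every analytic record must have.
REQUIRED_COVARIATES = ("sex", "age_band", "marital", "university", "n_jobs",
                       "residence", "region")

#: Default completeness requirement: covariates for everyone, employment
#: fields for working records (they do not apply to the unemployed).
DEFAULT_REQUIRED_FIELDS = REQUIRED_COVARIATES + sch.EMPLOYMENT_FIELDS


@dataclass
class SampleAudit:
    """Record counts at each stage of sample construction."""

    n_raw: int
    n_first_visit: int
    n_nurses: int
    n_complete: int

    @property
    def n_excluded_incomplete(self) -> int:
        return self.n_nurses - self.n_complete

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_first_visit": self.n_first_visit,
            "n_nurses": self.n_nurses,
            "n_complete": self.n_complete,
            "n_excluded_incomplete": self.n_excluded_incomplete,
        }

    def __post_init__(self):
        if not (self.n_raw >= self.n_first_visit >= self.n_nurses
                >= self.n_complete >= 0):
            raise ValueError(f"inconsistent audit counts: {self.as_dict()}")


def assign_period(year: int) -> PeriodBin:
    """Map a survey year to its government-period bin (total on 2005-2019)."""
    year = int(year)
    for bin_ in PERIOD_BINS:
        if year in bin_:
            return bin_
    raise DomainError(f"year {year} outside the study window 2005-2019")


def add_period_column(df: pd.DataFrame, out: str = "period") -> pd.DataFrame:
    df = df.copy()
    df[out] = df["year"].map(lambda y: assign_period(y).label)
    return df


def classify_labor_status(record) -> str:
    """Classify one economically active nurse record.

    ``record`` is any mapping with ``economically_active``, ``working``,
    ``available_and_seeking`` and ``in_health_sector`` entries.
    """
    if not bool(record["economically_active"]):
        raise DomainError(
            "labor status is defined only for economically active records")
    if bool(record["working"]):
        return "employed_health" if bool(record["in_health_sector"]) \
            else "underemployed"
    if bool(record["available_and_seeking"]):
        return "unemployed"
    raise DomainError(
        "economically active record neither working nor available/seeking")


def classify_labor_status_frame(df: pd.DataFrame,
                                out: str = "labor_status") -> pd.DataFrame:
    """Vectorized classification; adds a ``labor_status`` column."""
    if (df["economically_active"].fillna(0) == 0).any():
        raise DomainError("frame contains non-economically-active records")
    working = df["working"].fillna(0).astype(bool)
    seeking = df["available_and_seeking"].fillna(0).astype(bool)
    health = df["in_health_sector"].fillna(0).astype(bool)
    if ((~working) & (~seeking)).any():
        raise DomainError(
            "economically active record neither working nor available/seeking")
    df = df.copy()
    status = pd.Series("unemployed", index=df.index)
    status[working & health] = "employed_health"
    status[working & ~health] = "underemployed"
    df[out] = status
    return df


def build_analytic_sample(records: pd.DataFrame,
                          nurse_codes=sch.NURSE_CODES,
                          required_fields=DEFAULT_REQUIRED_FIELDS,
                          ) -> tuple[pd.DataFrame, SampleAudit]:
    """Apply the sample-construction rules; return (sample, audit).

    Stages: (1) first-visit households; (2) economically active nurses by
    occupation code; (3) complete records — no missing value among
    ``required_fields``, where the employment fields are required of working
    records only. Row order of the input is preserved (order-stable), so the
    operation is idempotent.
    """
    if not nurse_codes:
        raise ConfigurationError("nurse_codes must not be empty")
    unknown = [f for f in required_fields if f not in sch.COLUMNS]
    if unknown:
        raise ConfigurationError(f"unknown required fields: {unknown}")

    n_raw = len(records)
    fv = records[records["visit_number"] == 1]
    n_first_visit = len(fv)
    nurses = fv[
        fv["occupation_code"].isin(list(nurse_codes))
        & (fv["economically_active"].fillna(0) == 1)
    ]
    n_nurses = len(nurses)

    working = nurses["working"].fillna(0) == 1
    complete = pd.Series(True, index=nurses.index)
    for fieldname in required_fields:
        present = nurses[fieldname].notna()
        if fieldname in sch.EMPLOYMENT_FIELDS:
            complete &= present | ~working
        else:
            complete &= present
    sample = nurses[complete].copy()
    audit = SampleAudit(n_raw=n_raw, n_first_visit=n_first_visit,
                        n_nurses=n_nurses, n_complete=len(sample))
    return sample, audit
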