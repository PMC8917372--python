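"""The additive employment-precariousness score and the performance outcome.

Five dichotomous adverse-condition indicators are computed for every working
record (1 = the adverse condition holds):

* ``salary_flag`` — income up to two times the minimum wage (inclusive);
* ``workday_flag`` — works less than 34 or more than 48 hours per week
  (part-time or extended time); the 34-48 h band inclusive is unflagged;
* ``contract_flag`` — no written contract;
* ``benefits_flag`` — no social benefit at all;
* ``social_security_flag`` — no access to health services from
  social-security institutions.

Their non-weighted sum is the 0-5 precariousness score. A score of zero
while employed in the health sector defines the non-precarious-employment
outcome, the study's headline labor-market performance proxy. A two-level
summary ("non- or low-precarious" vs "highly precarious") cuts the score at
a configurable threshold (default 3: a majority of components adverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .schema import EMPLOYMENT_FIELDS

FLAG_COLUMNS = ("salary_flag", "workday_flag", "contract_flag",
                "benefits_flag", "social_security_flag")

LEVELS = ("non_or_low", "high")

#: Five-way status used in descriptive cross-tabulations.
FIVE_WAY_STATUSES = ("unemployed", "underemployed_nonprecarious",
                     "underemployed_precarious", "employed_nonprecarious",
                     "employed_precarious")


@dataclass
class PrecarityConfig:
    """Thresholds of the five indicator rules.

    salary_mw_cut: flagged iff income <= this multiple of the minimum wage.
    hours_low/hours_high: flagged iff weekly hours < hours_low or > hours_high.
    high_cut: score >= high_cut is 'highly precarious'.
    """

    salary_mw_cut: float = 2.0
    hours_low: float = 34.0
    hours_high: float = 48.0
    high_cut: int = 3

    def validate(self):
        if not 1 <= self.high_cut <= 5:
            raise ValidationError("high_cut must be in 1..5")
        if self.salary_mw_cut <= 0 or self.hours_low < 0 \
                or self.hours_high < self.hours_low:
            raise ValidationError("invalid precarity thresholds")


@dataclass
class PrecarityComponents:
    salary_flag: int
    workday_flag: int
    contract_flag: int
    benefits_flag: int
    social_security_flag: int

    @property
    def score(self) -> int:
        return (self.salary_flag + self.workday_flag + self.contract_flag
                + self.benefits_flag + self.social_security_flag)

    def level(self, high_cut: int = 3) -> str:
        return classify_precarity_level(self.score, high_cut)


def income_to_mw(income_currency: float, year: int, mw_table: dict) -> float:
    """Convert a currency income to minimum-wage multiples (real-data path)."""
    if year not in mw_table:
        raise DomainError(f"no minimum wage configured for year {year}")
    mw = float(mw_table[year])
    if mw <= 0:
        raise ValidationError("minimum wage must be positive")
    return float(income_currency) / mw


def precarity_components(record, config: PrecarityConfig | None = None
                         ) -> PrecarityComponents:
    """Score one working record (mapping with the employment fields).

    ``income_mw`` must already be expressed as a multiple of the minimum
    wage (use :func:`income_to_mw` for currency incomes).
    """
    config = config or PrecarityConfig()
    config.validate()
    if not bool(record["working"]):
        raise DomainError("precarity is defined only for working records")
    hours = float(record["weekly_hours"])
    income = float(record["income_mw"])
    if hours < 0 or income < 0:
        raise ValidationError("hours and income must be non-negative")
    return PrecarityComponents(
        salary_flag=int(income <= config.salary_mw_cut),
        workday_flag=int(hours < config.hours_low or hours > config.hours_high),
        contract_flag=int(not bool(record["written_contract"])),
        benefits_flag=int(not bool(record["any_social_benefit"])),
        social_security_flag=int(not bool(record["ss_health_access"])),
    )


def classify_precarity_level(score: int, high_cut: int = 3) -> str:
    if not 0 <= score <= 5:
        raise ValidationError(f"score {score} outside 0..5")
    if not 1 <= high_cut <= 5:
        raise ValidationError(f"high_cut {high_cut} outside 1..5")
    return "high" if score >= high_cut else "non_or_low"


def market_performance_outcome(record, components: PrecarityComponents,
                               status: str) -> int:
    """1 iff employed in the health sector with a zero score."""
    if status == "unemployed":
        raise DomainError("the outcome is undefined for unemployed records")
    return int(status == "employed_health" and components.score == 0)


def add_precarity_columns(df: pd.DataFrame,
                          config: PrecarityConfig | None = None,
                          status_col: str = "labor_status") -> pd.DataFrame:
    """Vectorized scoring of a classified analytic sample.

    Adds the five flags, ``score`` and ``level`` (NA for non-working
    records) and, when ``status_col`` is present, the binary
    ``non_precarious_employment`` outcome (NA for the unemployed).
    """
    config = config or PrecarityConfig()
    config.validate()
    df = df.copy()
    working = df["working"].fillna(0).astype(bool)
    w = df[working]
    if (w["weekly_hours"] < 0).any() or (w["income_mw"] < 0).any():
        raise ValidationError("hours and income must be non-negative")
    if w[list(EMPLOYMENT_FIELDS)].isna().any().any():
        raise ValidationError(
            "working records with missing employment fields cannot be scored; "
            "exclude them first (build_analytic_sample)")

    flags = pd.DataFrame(index=df.index, columns=list(FLAG_COLUMNS),
                         dtype="float")
    flags.loc[working, "salary_flag"] = (
        w["income_mw"] <= config.salary_mw_cut).astype(float)
    flags.loc[working, "workday_flag"] = (
        (w["weekly_hours"] < config.hours_low)
        | (w["weekly_hours"] > config.hours_high)).astype(float)
    flags.loc[working, "contract_flag"] = (
        w["written_contract"].astype(float) == 0).astype(float)
    flags.loc[working, "benefits_flag"] = (
        w["any_social_benefit"].astype(float) == 0).astype(float)
    flags.loc[working, "social_security_flag"] = (
        w["ss_health_access"].astype(float) == 0).astype(float)

    for col in FLAG_COLUMNS:
        df[col] = flags[col].astype("Int8")
    df["score"] = flags.sum(axis=1, skipna=False).astype("Int8")
    level = pd.Series(pd.NA, index=df.index, dtype="object")
    level[working] = np.where(df.loc[working, "score"] >= config.high_cut,
                              "high", "non_or_low")
    df["level"] = level

    if status_col in df.columns:
        status = df[status_col]
        outcome = pd.Series(pd.NA, index=df.index, dtype="object")
        notun = status != "unemployed"
        outcome[notun] = ((status[notun] == "employed_health")
                          & (df.loc[notun, "score"] == 0)).astype(int)
        df["non_precarious_employment"] = outcome.astype("Int8")
    return df


def five_way_status(df: pd.DataFrame, status_col: str = "labor_status",
                    out: str = "status5") -> pd.DataFrame:
    """Combine labor status with precarious (score >= 1) vs non-precarious."""
    df = df.copy()
    status = df[status_col]
    prec = df["score"].astype("Float64") > 0
    s5 = pd.Series(pd.NA, index=df.index, dtype="object")
    s5[status == "unemployed"] = "unemployed"
    s5[(status == "underemployed") & ~prec] = "underemployed_nonprecarious"
    s5[(status == "underemployed") & prec] = "underemployed_precarious"
    s5[(status == "employed_health") & ~prec] = "employed_nonprecarious"
    s5[(status == "employed_health") & prec] = "employed_precarious"
    df[out] = s5
    return df
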