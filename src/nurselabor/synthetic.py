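"""Synthetic rotating-panel labor-force microdata with known ground truth.

The generator emulates the occupation-screened extract of a quarterly,
rotating-panel household labor-force survey (households are interviewed for
five consecutive quarters; one fifth of the sample rotates in each quarter).
Every downstream stage — first-visit sample selection, labor-status
classification, precariousness scoring, design-based estimation and
survey-weighted regression — can therefore be tested against parameters the
generator knows exactly.

Data-generating process
-----------------------
* Households enter in quarterly cohorts; a household entering at quarter
  ``t`` is observed with ``visit_number`` 1..5 at quarters ``t..t+4``, so
  after burn-in about 20% of households in any quarter are first visits.
  Household members are drawn fresh each quarter (no longitudinal linkage;
  only first visits are analyzed downstream).
* Each person carries design variables (stratum, PSU, log-normal expansion
  weight), sociodemographic covariates drawn from configurable categorical
  distributions, and an occupation code (nurse with probability
  ``nurse_fraction``).
* Economically active nurses receive a labor status (unemployed /
  underemployed / employed in the health sector) from per-period
  probabilities.
* For every working record, each of the five precariousness components is
  drawn from an independent logistic model: the linear predictor
  ``eta_k = b0 + b_public*public + b_trend*(year - y0) + b_univ*university
  + b_male*male`` gives the probability ``expit(eta_k)`` of being
  NON-precarious on component ``k``; the adverse flag is the complement.
  Raw fields (income, hours, contract, benefits, social security) are then
  synthesized consistently with the drawn flags, so recomputing the flags
  from raw fields must reproduce them. Independence across components makes
  the probability of a zero score factorizable:
  ``P(score = 0 | x) = prod_k expit(eta_k(x))``.
* Missingness: with probability ``missing_rate`` a working record gets one
  of the five employment fields blanked (chosen uniformly), emulating the
  survey's incomplete records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import schema as sch
from .exceptions import ConfigurationError

COMPONENTS = ("salary", "workday", "contract", "benefits", "social_security")

#: features recognized in a component's non-precarity linear predictor
_COEF_FEATURES = ("intercept", "public", "year_trend", "university", "male")

ALL_QUARTERS = tuple((y, q) for y in range(2005, 2020) for q in (1, 2, 3, 4))

#: Per-period (unemployed, underemployed, employed-in-health) probabilities
#: for economically active nurses. Chosen to echo the published series:
#: unemployment flat near 5%, underemployment rising 26.7% -> 33.7%,
#: health-sector employment falling 68.6% -> 61.4% between the first and
#: last periods.
DEFAULT_LABOR_STATUS_PROBS = {
    "2005-2006": (0.047, 0.267, 0.686),
    "2007-2009": (0.050, 0.285, 0.665),
    "2010-2012": (0.051, 0.300, 0.649),
    "2013-2015": (0.050, 0.312, 0.638),
    "2016-2018": (0.050, 0.325, 0.625),
    "2019": (0.049, 0.337, 0.614),
}

#: Default non-precarity propensities. Intercepts and sector effects are set
#: so the composite zero-score probability among health-sector employees is
#: about 0.60 in the public and 0.31 in the private sector at the start of
#: the period, with a slow deterioration over the years — the qualitative
#: pattern of the published cross-tabulations.
DEFAULT_DGP_COEFS = {
    "salary": {"intercept": 1.2, "public": 0.9, "year_trend": -0.03,
               "university": 0.25, "male": -0.05},
    "workday": {"intercept": 1.6, "public": 0.5, "year_trend": -0.02,
                "university": 0.10, "male": -0.10},
    "contract": {"intercept": 1.2, "public": 1.4, "year_trend": -0.04,
                 "university": 0.30, "male": -0.10},
    "benefits": {"intercept": 1.4, "public": 1.2, "year_trend": -0.03,
                 "university": 0.20, "male": -0.05},
    "social_security": {"intercept": 1.3, "public": 1.3, "year_trend": -0.03,
                        "university": 0.20, "male": -0.05},
}

DEFAULT_COVARIATE_DISTS = {
    "sex": {"female": 0.91, "male": 0.09},
    "age_band": {"24_or_less": 0.15, "25_54": 0.75, "55_plus": 0.10},
    "marital": {"married_union": 0.55, "single": 0.35, "divorced_widowed": 0.10},
    "university": {"yes": 0.45, "no": 0.55},
    "n_jobs": {"one": 0.95, "two_plus": 0.05},
    "residence": {"rural": 0.08, "semi_urban": 0.10, "urban": 0.17,
                  "metropolitan": 0.65},
    "region": {"1": 0.14, "2": 0.15, "3": 0.13, "4": 0.16, "5": 0.20, "6": 0.22},
}


def _default_quarters():
    return list(ALL_QUARTERS)


def _default_dists():
    return {k: dict(v) for k, v in DEFAULT_COVARIATE_DISTS.items()}


def _default_coefs():
    return {k: dict(v) for k, v in DEFAULT_DGP_COEFS.items()}


def _default_status_probs():
    return dict(DEFAULT_LABOR_STATUS_PROBS)


@dataclass
class SimulationParams:
    """Ground-truth parameters of the synthetic survey.

    Defaults are sized so a full 2005-2019 run yields roughly 22,000
    economically active first-visit nurses (about 19,000 after removing
    incomplete records), matching the scale of the study the generator
    emulates. ``nurse_fraction`` is high because the generator emulates the
    occupation-screened extract, not the whole population survey.
    """

    n_households_per_quarter: int = 1875
    quarters: list = field(default_factory=_default_quarters)
    nurse_fraction: float = 0.5
    covariate_dists: dict = field(default_factory=_default_dists)
    n_strata: int = 32
    psus_per_stratum: int = 6
    weight_mean: float = 250.0
    weight_sigma: float = 0.5
    mean_household_size: float = 2.0
    p_econ_active: float = 0.97
    p_public_employed: float = 0.60
    p_public_underemployed: float = 0.25
    dgp_coefs: dict = field(default_factory=_default_coefs)
    labor_status_probs: dict = field(default_factory=_default_status_probs)
    missing_rate: float = 0.12
    seed: int = 20050101

    def validate(self) -> None:
        if self.n_households_per_quarter < 5:
            raise ConfigurationError("need at least 5 households per quarter")
        if not self.quarters:
            raise ConfigurationError("quarters list is empty")
        keys = [(y, q) for y, q in self.quarters]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise ConfigurationError("quarters must be strictly increasing")
        for y, q in keys:
            if not (2005 <= y <= 2019 and q in (1, 2, 3, 4)):
                raise ConfigurationError(f"quarter out of range: {(y, q)}")
        if not 0.0 < self.nurse_fraction <= 1.0:
            raise ConfigurationError("nurse_fraction must be in (0, 1]")
        for prob in (self.p_econ_active, self.p_public_employed,
                     self.p_public_underemployed, self.missing_rate):
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        for name, dist in self.covariate_dists.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"covariate distribution {name!r} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"negative probability in {name!r}")
        if self.weight_mean <= 0:
            raise ConfigurationError("weight_mean must be positive")
        if set(self.dgp_coefs) != set(COMPONENTS):
            raise ConfigurationError(
                f"dgp_coefs must have exactly the components {COMPONENTS}")
        for comp, coefs in self.dgp_coefs.items():
            unknown = set(coefs) - set(_COEF_FEATURES)
            if unknown:
                raise ConfigurationError(
                    f"unknown coefficient features for {comp!r}: {sorted(unknown)}")
        for label, probs in self.labor_status_probs.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(
                    f"labor_status_probs[{label!r}] must be 3 probabilities summing to 1")

    @property
    def first_year(self) -> int:
        return min(y for y, _ in self.quarters)


def _period_label(year: int) -> str:
    # local import avoids a module cycle (cohort imports nothing from here)
    from .cohort import assign_period

    return assign_period(year).label


def _draw_categorical(rng, dist: dict, n: int) -> np.ndarray:
    cats = np.array(list(dist.keys()))
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return cats[rng.choice(len(cats), size=n, p=probs)]


def component_linear_predictor(coefs: dict, public, years_since_start,
                               university, male):
    """Non-precarity linear predictor eta_k for one component (vectorized)."""
    return (
        coefs.get("intercept", 0.0)
        + coefs.get("public", 0.0) * np.asarray(public, dtype=float)
        + coefs.get("year_trend", 0.0) * np.asarray(years_since_start, dtype=float)
        + coefs.get("university", 0.0) * np.asarray(university, dtype=float)
        + coefs.get("male", 0.0) * np.asarray(male, dtype=float)
    )


def generate_microdata(params: SimulationParams) -> pd.DataFrame:
    """Generate the person-quarter microdata frame (schema of :mod:`.schema`).

    Deterministic given ``params.seed``: identical parameters yield a
    byte-identical CSV.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    y0 = params.first_year

    n_hh = params.n_households_per_quarter
    base = n_hh // 5
    cohort_sizes = [base + (1 if r < n_hh % 5 else 0) for r in range(5)]

    frames = []
    for t, (year, quarter) in enumerate(params.quarters):
        status_probs = np.array(
            params.labor_status_probs.get(
                _period_label(year),
                DEFAULT_LABOR_STATUS_PROBS[_period_label(year)],
            ),
            dtype=float,
        )
        for age in range(5):  # panel age: 0 = entered this quarter (visit 1)
            cohort = t - age
            m = cohort_sizes[(-cohort) % 5]
            visit = age + 1
            hh_index = np.arange(m)
            hh_ids = np.char.add(f"C{cohort + 4:04d}H", np.char.zfill(
                hh_index.astype(str), 5))
            stratum = rng.integers(0, params.n_strata, size=m)
            psu = rng.integers(0, params.psus_per_stratum, size=m)
            sizes = 1 + rng.poisson(max(params.mean_household_size - 1.0, 0.0),
                                    size=m)
            n = int(sizes.sum())
            hh_rep = np.repeat(hh_ids, sizes)
            stratum_rep = np.repeat(stratum, sizes)
            psu_rep = np.repeat(psu, sizes)
            within = np.concatenate([np.arange(s) for s in sizes])
            person_ids = np.char.add(
                np.char.add(hh_rep.astype(str), f"Q{t:03d}P"),
                within.astype(str))

            mu = math.log(params.weight_mean) - params.weight_sigma ** 2 / 2
            weight = rng.lognormal(mu, params.weight_sigma, size=n)

            sex = _draw_categorical(rng, params.covariate_dists["sex"], n)
            age_band = _draw_categorical(rng, params.covariate_dists["age_band"], n)
            marital = _draw_categorical(rng, params.covariate_dists["marital"], n)
            university = (
                _draw_categorical(rng, params.covariate_dists["university"], n)
                == "yes").astype(int)
            n_jobs = _draw_categorical(rng, params.covariate_dists["n_jobs"], n)
            residence = _draw_categorical(rng, params.covariate_dists["residence"], n)
            region = _draw_categorical(rng, params.covariate_dists["region"], n
                                       ).astype(int)

            is_nurse = rng.random(n) < params.nurse_fraction
            occ = np.where(is_nurse,
                           np.where(rng.random(n) < 0.5, "N111", "N112"),
                           "X999")
            active = np.where(is_nurse,
                              rng.random(n) < params.p_econ_active,
                              rng.random(n) < 0.65)

            # labor status: 0 unemployed, 1 underemployed, 2 employed-health
            status = np.full(n, -1)
            nurse_active = is_nurse & active
            k = int(nurse_active.sum())
            if k:
                status[nurse_active] = rng.choice(3, size=k, p=status_probs)
            other_active = ~is_nurse & active
            # non-nurses: working if active; a few work in the health sector
            status[other_active] = np.where(
                rng.random(int(other_active.sum())) < 0.05, 2, 1)

            working = np.isin(status, (1, 2)).astype(int)
            seeking = np.zeros(n, dtype=int)
            seeking[status == 0] = 1
            seeking[working == 1] = (rng.random(int(working.sum())) < 0.10
                                     ).astype(int)
            in_health = (status == 2).astype(int)

            p_public = np.where(status == 2, params.p_public_employed,
                                params.p_public_underemployed)
            public = (rng.random(n) < p_public) & (working == 1)
            sector = np.where(working == 1,
                              np.where(public, "public", "private"), "none")

            male = (sex == "male").astype(int)
            yrs = float(year - y0)
            flags = {}
            for comp in COMPONENTS:
                eta = component_linear_predictor(
                    params.dgp_coefs[comp], public.astype(int), yrs,
                    university, male)
                nonprec = rng.random(n) < expit(eta)
                flags[comp] = np.where(working == 1, (~nonprec).astype(int), 0)

            # synthesize raw fields consistent with the drawn flags
            income = np.where(flags["salary"] == 1,
                              rng.uniform(0.3, 2.0, size=n),
                              rng.uniform(2.01, 10.0, size=n))
            short_day = rng.random(n) < 0.5
            hours = np.where(
                flags["workday"] == 1,
                np.where(short_day, rng.uniform(4.0, 33.9, size=n),
                         rng.uniform(48.1, 80.0, size=n)),
                rng.uniform(34.0, 48.0, size=n))
            income = np.where(working == 1, np.round(income, 3), 0.0)
            hours = np.where(working == 1, np.round(hours, 1), 0.0)
            contract = np.where(working == 1, 1 - flags["contract"], np.nan)
            benefit = np.where(working == 1, 1 - flags["benefits"], np.nan)
            ss = np.where(working == 1, 1 - flags["social_security"], np.nan)

            income = income.astype(object)
            hours = hours.astype(object)
            contract = contract.astype(object)
            benefit = benefit.astype(object)
            ss = ss.astype(object)
            if params.missing_rate > 0:
                hit = (rng.random(n) < params.missing_rate) & (working == 1)
                which = rng.integers(0, len(sch.EMPLOYMENT_FIELDS), size=n)
                holders = {"income_mw": income, "weekly_hours": hours,
                           "written_contract": contract,
                           "any_social_benefit": benefit,
                           "ss_health_access": ss}
                for j, fname in enumerate(sch.EMPLOYMENT_FIELDS):
                    holders[fname][hit & (which == j)] = np.nan
            else:
                # keep the rng stream identical across missing-rate settings
                rng.random(n)
                rng.integers(0, len(sch.EMPLOYMENT_FIELDS), size=n)

            frames.append(pd.DataFrame({
                "household_id": hh_rep,
                "person_id": person_ids,
                "year": year,
                "quarter": quarter,
                "visit_number": visit,
                "stratum_id": stratum_rep,
                "psu_id": psu_rep,
                "weight": np.round(weight, 4),
                "occupation_code": occ,
                "economically_active": active.astype(int),
                "working": working,
                "available_and_seeking": seeking,
                "sector": sector,
                "in_health_sector": in_health,
                "weekly_hours": hours,
                "income_mw": income,
                "written_contract": contract,
                "any_social_benefit": benefit,
                "ss_health_access": ss,
                "sex": sex,
                "age_band": age_band,
                "marital": marital,
                "university": university,
                "n_jobs": n_jobs,
                "residence": residence,
                "region": region,
            }))

    df = pd.concat(frames, ignore_index=True)
    for col in ("weekly_hours", "income_mw", "written_contract",
                "any_social_benefit", "ss_health_access"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return sch.coerce_dtypes(df)


# -- ground truth -------------------------------------------------------------

@dataclass
class GroundTruth:
    """Monte-Carlo summary of the generator's implied parameters.

    ``p_nonprecarious`` has one row per (sector, year) with the marginal
    probability of a zero precariousness score among workers of that sector
    and year (integrated over the covariate distribution).
    ``sector_or_conditional`` is the mean over covariate draws of the
    conditional public-vs-private odds ratio of a zero score at the first
    year; for a single-component process it equals exp(beta_public) exactly.
    """

    p_nonprecarious: pd.DataFrame
    sector_or_conditional: float
    n_draws: int


def expected_truth(params: SimulationParams, n_draws: int = 100_000,
                   seed: int | None = None) -> GroundTruth:
    """Integrate the component models over the covariate distribution.

    Deterministic given ``seed`` (defaults to ``params.seed + 1``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    university = (_draw_categorical(rng, params.covariate_dists["university"],
                                    n_draws) == "yes").astype(int)
    male = (_draw_categorical(rng, params.covariate_dists["sex"], n_draws)
            == "male").astype(int)
    years = sorted({y for y, _ in params.quarters})
    y0 = params.first_year

    rows = []
    p_by = {}
    for year in years:
        for sector, pub in (("public", 1), ("private", 0)):
            p0 = np.ones(n_draws)
            for comp in COMPONENTS:
                eta = component_linear_predictor(
                    params.dgp_coefs[comp], pub, year - y0, university, male)
                p0 = p0 * expit(eta)
            p_by[(sector, year)] = p0
            rows.append({"sector": sector, "year": year,
                         "p_nonprecarious": float(p0.mean())})

    pub0 = np.clip(p_by[("public", y0)], 1e-12, 1 - 1e-12)
    priv0 = np.clip(p_by[("private", y0)], 1e-12, 1 - 1e-12)
    cond_or = float(np.mean((pub0 / (1 - pub0)) / (priv0 / (1 - priv0))))
    table = pd.DataFrame(rows)
    return GroundTruth(p_nonprecarious=table, sector_or_conditional=cond_or,
                       n_draws=n_draws)


def single_component_params(beta_sector: float = math.log(7.0),
                            intercept: float = -0.4,
                            year_trend: float = -0.05,
                            **overrides) -> SimulationParams:
    """Parameters whose zero-score outcome is *exactly* logistic.

    Four components are forced to 'never precarious' (non-precarity
    propensity +30 on the logit scale); the salary component alone carries
    the sector effect, so ``logit P(score=0) = intercept +
    beta_sector*public + year_trend*(year - y0)`` and the conditional
    public-vs-private odds ratio is exp(beta_sector). Used for
    parameter-recovery studies.
    """
    coefs = {comp: {"intercept": 30.0} for comp in COMPONENTS}
    coefs["salary"] = {"intercept": intercept, "public": beta_sector,
                       "year_trend": year_trend}
    params = SimulationParams(dgp_coefs=coefs, **overrides)
    return params


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    return replace(params, seed=int(seed))
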