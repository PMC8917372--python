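"""Replicated simulation studies: parameter recovery and GOF calibration.

These experiments validate the estimation machinery against the synthetic
generator's known ground truth. They are part of the package (not only of
its tests) so that the same audited code produces the reproducibility
report numbers.

Problem sizes follow the package's validation protocol: sector-effect
recovery uses replicates of about 20,000 health-sector employees drawn from
a single-component process whose zero-score outcome is exactly logistic
(conditional public-vs-private odds ratio exp(beta_sector)); goodness-of-fit
calibration uses a correctly specified weighted logistic model with a
continuous covariate, and power uses the same model with a strong omitted
quadratic term.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import build_analytic_sample, classify_labor_status_frame
from .models import (archer_lemeshow_gof, build_model_spec, fit_logit_arrays,
                     fit_survey_logit, select_sample)
from .precarity import add_precarity_columns
from .survey import SurveyDesign
from .synthetic import generate_microdata, single_component_params


def recovery_replicate_params(beta_sector: float = math.log(7.0),
                              n_target: int = 20_000, seed: int = 0):
    """Generator parameters for one sector-recovery replicate.

    Two survey years (eight quarters) keep the year and sector-by-year
    factors in the model while the household count is sized so the
    first-visit employed sample is about ``n_target`` records.
    """
    quarters = [(y, q) for y in (2005, 2006) for q in (1, 2, 3, 4)]
    per_quarter = max(int(round(n_target / (len(quarters) * 2 * 0.2))), 25)
    return single_component_params(
        beta_sector=beta_sector,
        quarters=quarters,
        n_households_per_quarter=per_quarter,
        nurse_fraction=1.0,
        p_econ_active=1.0,
        missing_rate=0.0,
        labor_status_probs={"2005-2006": (0.0, 0.0, 1.0)},
        seed=seed,
    )


@dataclass
class RecoveryResult:
    coverage: float          # share of replicates whose 95% CI covers truth
    bias: float              # mean (beta_hat - beta_true)
    mean_n: float
    n_replicates: int
    beta_true: float


def sector_recovery_study(n_replicates: int = 200, seed: int = 0,
                          beta_sector: float = math.log(7.0),
                          n_target: int = 20_000) -> RecoveryResult:
    """Coverage and bias of the sector log-odds-ratio estimator.

    Each replicate regenerates microdata, rebuilds the analytic sample,
    rescores it and refits the level-1 model on the health-sector-employee
    sample; the reported coverage is of the t-based 95% CI for the
    reference-year sector coefficient.
    """
    rng = np.random.default_rng(seed)
    base = recovery_replicate_params(beta_sector, n_target)
    design = SurveyDesign()
    spec = build_model_spec("employed_only", 1)
    covered, biases, sizes = 0, [], []
    for _ in range(n_replicates):
        params = dataclasses.replace(
            base, seed=int(rng.integers(0, 2**31 - 1)))
        micro = generate_microdata(params)
        sample, _ = build_analytic_sample(micro)
        sample = classify_labor_status_frame(sample)
        sample = add_precarity_columns(sample)
        sub = select_sample(sample, "employed_only")
        fit = fit_survey_logit(sub, spec, design)
        beta = float(fit.beta["sector_public"])
        se = float(fit.se()["sector_public"])
        tcrit = stats.t.ppf(0.975, fit.df_design)
        covered += int(beta - tcrit * se <= beta_sector <= beta + tcrit * se)
        biases.append(beta - beta_sector)
        sizes.append(fit.n_obs)
    return RecoveryResult(coverage=covered / n_replicates,
                          bias=float(np.mean(biases)),
                          mean_n=float(np.mean(sizes)),
                          n_replicates=n_replicates,
                          beta_true=beta_sector)


def _gof_replicate(rng, n: int, misspecified: bool,
                   n_strata: int = 32, psus: int = 6) -> float:
    """One GOF replicate: fit a weighted logit, return the AL p-value.

    Correct specification: logit p = -0.3 + 0.8 x, model fits (1, x).
    Misspecified: the data add a strong quadratic 1.5 x - 1.2 x^2 that the
    fitted model omits.
    """
    x = rng.normal(0.0, 1.0, n)
    eta = -0.3 + 0.8 * x
    if misspecified:
        eta = eta + 1.5 * x - 1.2 * x * x
    y = (rng.random(n) < expit(eta)).astype(float)
    strata = rng.integers(0, n_strata, n).astype(str)
    psu = np.char.add(np.char.add(strata, "|"),
                      rng.integers(0, psus, n).astype(str))
    w = rng.lognormal(0.0, 0.4, n)
    X = np.column_stack([np.ones(n), x])
    fit = fit_logit_arrays(X, y, w, strata, psu, names=["intercept", "x"])
    return archer_lemeshow_gof(fit, n_groups=10).p_value


@dataclass
class GofCalibrationResult:
    type1_rate: float
    power: float
    n_type1: int
    n_power: int
    alpha: float


def gof_calibration_study(n_type1: int = 500, n_power: int = 150,
                          seed: int = 0, alpha: float = 0.05,
                          n_correct: int = 2000,
                          n_miss: int = 10_000) -> GofCalibrationResult:
    """Type-I error under correct specification and power under a strong
    omitted quadratic, for the F-adjusted Hosmer-Lemeshow test."""
    rng = np.random.default_rng(seed)
    p1 = [_gof_replicate(rng, n_correct, False) for _ in range(n_type1)]
    p2 = [_gof_replicate(rng, n_miss, True) for _ in range(n_power)]
    return GofCalibrationResult(
        type1_rate=float(np.mean(np.asarray(p1) < alpha)),
        power=float(np.mean(np.asarray(p2) < alpha)),
        n_type1=n_type1, n_power=n_power, alpha=alpha)
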