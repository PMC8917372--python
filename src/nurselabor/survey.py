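"""Design-based estimation under stratified cluster sampling.

Weighted proportions and cross-tabulations with Taylor-linearized
(between-PSU) variances, t-based confidence intervals and correct
subpopulation (domain) analysis: out-of-domain records contribute zero to
the linearized totals but the full design — every stratum and PSU — is
retained in the variance, as required for design-consistent domain
estimation.

Notation: for weights ``w_i``, domain indicator ``d_i`` and binary outcome
``y_i``, the ratio estimator is ``p = sum(w d y) / sum(w d)`` with
linearized score ``u_i = w_i d_i (y_i - p) / sum(w d)``. PSU totals of
``u_i`` enter the standard stratified between-cluster variance

    V = sum_h n_h/(n_h - 1) * sum_j (t_hj - tbar_h)^2,

with design degrees of freedom ``df = (#PSUs) - (#strata)``. Confidence
intervals for proportions are computed on the logit scale with a t(df)
critical value and back-transformed (plain Wald available as an option);
degenerate estimates of 0 or 1 get a one-sided exact-style bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError

logger = logging.getLogger(__name__)


@dataclass
class SurveyDesign:
    """Columns identifying the complex-sample design.

    ``single_psu`` controls strata with a lone PSU: ``"error"`` (default)
    raises; ``"collapse"`` pools all single-PSU strata into one synthetic
    stratum (a pragmatic rule for real data).
    """

    stratum_col: str = "stratum_id"
    psu_col: str = "psu_id"
    weight_col: str = "weight"
    single_psu: str = "error"

    def layout(self, df: pd.DataFrame):
        """Return (stratum codes, psu codes, weights) as aligned arrays."""
        strata = df[self.stratum_col].astype(str).to_numpy()
        # PSU ids are only unique within stratum; build global PSU labels
        psu = np.char.add(np.char.add(strata, "|"),
                          df[self.psu_col].astype(str).to_numpy())
        w = df[self.weight_col].to_numpy(dtype=float)
        if (w <= 0).any():
            raise ConfigurationError("all weights must be strictly positive")

        counts = pd.DataFrame({"s": strata, "p": psu}).groupby("s")["p"].nunique()
        singles = counts[counts < 2].index
        if len(singles) > 0:
            if self.single_psu == "collapse":
                pooled = set(singles)
                if len(pooled) < 2:
                    raise ConfigurationError(
                        "cannot collapse: fewer than two single-PSU strata")
                strata = np.where(np.isin(strata, list(pooled)),
                                  "_collapsed", strata)
            else:
                raise ConfigurationError(
                    f"strata with a single PSU: {sorted(singles)[:5]} "
                    "(variance undefined; enable single_psu='collapse')")
        return strata, psu, w

    def degrees_of_freedom(self, df: pd.DataFrame) -> int:
        strata, psu, _ = self.layout(df)
        return len(np.unique(psu)) - len(np.unique(strata))


@dataclass
class EstimateWithCI:
    """A design-based point estimate with its 95% interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    n_weighted: float

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n": self.n_unweighted, "N": self.n_weighted}


def stratified_cluster_variance(u: np.ndarray, strata: np.ndarray,
                                psu: np.ndarray):
    """Between-PSU variance of a linearized total; works column-wise.

    ``u`` is (n,) or (n, k): per-record linearized contributions. Returns a
    scalar (k=absent) or a (k, k) covariance matrix.
    """
    u = np.asarray(u, dtype=float)
    squeeze = u.ndim == 1
    if squeeze:
        u = u[:, None]
    frame = pd.DataFrame(u)
    frame["_s"] = strata
    frame["_p"] = psu
    totals = frame.groupby(["_s", "_p"], sort=True).sum()
    cov = np.zeros((u.shape[1], u.shape[1]))
    for _, block in totals.groupby(level=0, sort=True):
        t = block.to_numpy()
        n_h = t.shape[0]
        if n_h < 2:
            raise ConfigurationError("stratum with a single PSU in variance")
        dev = t - t.mean(axis=0, keepdims=True)
        cov += n_h / (n_h - 1) * dev.T @ dev
    return cov[0, 0] if squeeze else cov


def _proportion_ci(p: float, se: float, df: int, n: int, alpha: float,
                   method: str):
    if p <= 0.0:
        return 0.0, 1.0 - (alpha / 2) ** (1.0 / max(n, 1))
    if p >= 1.0:
        return (alpha / 2) ** (1.0 / max(n, 1)), 1.0
    tcrit = stats.t.ppf(1 - alpha / 2, max(df, 1))
    if method == "wald":
        return max(p - tcrit * se, 0.0), min(p + tcrit * se, 1.0)
    if method != "logit":
        raise ConfigurationError(f"unknown CI method {method!r}")
    lo = np.log(p / (1 - p))
    se_l = se / (p * (1 - p))
    lo_l, hi_l = lo - tcrit * se_l, lo + tcrit * se_l
    return float(1 / (1 + np.exp(-lo_l))), float(1 / (1 + np.exp(-hi_l)))


def weighted_proportion(df: pd.DataFrame, indicator, design: SurveyDesign,
                        domain=None, alpha: float = 0.05,
                        ci_method: str = "logit") -> EstimateWithCI:
    """Design-based proportion of ``indicator`` within ``domain``.

    ``indicator``: column name or boolean/0-1 Series aligned with ``df``;
    it must be defined (non-missing) on every domain record. ``domain``:
    optional boolean Series; the full design is retained for the variance.
    """
    strata, psu, w = design.layout(df)
    y = (df[indicator] if isinstance(indicator, str) else indicator)
    y = pd.Series(np.asarray(y, dtype="float"), index=df.index)
    if domain is None:
        d = np.ones(len(df), dtype=float)
    else:
        d = np.asarray(domain, dtype=bool).astype(float)
    if d.sum() == 0:
        raise DomainError("empty estimation domain")
    if y[d.astype(bool)].isna().any():
        raise DomainError("indicator missing on some domain records")
    yv = y.fillna(0.0).to_numpy()

    wd = w * d
    W = wd.sum()
    p = float((wd * yv).sum() / W)
    u = wd * (yv - p) / W
    var = stratified_cluster_variance(u, strata, psu)
    se = float(np.sqrt(max(var, 0.0)))
    dof = len(np.unique(psu)) - len(np.unique(strata))
    n_dom = int(d.sum())
    ci_low, ci_high = _proportion_ci(p, se, dof, n_dom, alpha, ci_method)
    return EstimateWithCI(estimate=p, se=se, ci_low=ci_low, ci_high=ci_high,
                          n_unweighted=n_dom, n_weighted=float(W))


def labor_status_distribution(df: pd.DataFrame, design: SurveyDesign,
                              by: str = "period",
                              status_col: str = "labor_status") -> pd.DataFrame:
    """Per-period weighted shares of the three labor statuses (tidy table)."""
    from .cohort import LABOR_STATUSES

    rows = []
    for period in sorted(df[by].dropna().unique()):
        dom = df[by] == period
        if not dom.any():
            logger.warning("period %s has no records; omitted", period)
            continue
        for status in LABOR_STATUSES:
            est = weighted_proportion(df, (df[status_col] == status).astype(float),
                                      design, domain=dom)
            rows.append({by: period, "status": status, **est.as_dict()})
    return pd.DataFrame(rows)


def weighted_crosstab(df: pd.DataFrame, row_vars, col_var: str,
                      design: SurveyDesign) -> pd.DataFrame:
    """Tidy weighted cross-tabulation: for each category of each row
    variable (the domain), the share in each ``col_var`` category.

    Cells whose domain contains no record with that column value get share 0;
    domains that are empty altogether are omitted with a warning.
    """
    col_values = [v for v in df[col_var].dropna().unique()]
    col_values.sort()
    rows = []
    for var in row_vars:
        for cat in sorted(df[var].dropna().unique(), key=str):
            dom = df[var] == cat
            if not dom.any():
                logger.warning("empty domain %s=%s; omitted", var, cat)
                continue
            for cv in col_values:
                ind = (df[col_var] == cv).astype(float)
                est = weighted_proportion(df, ind, design, domain=dom)
                rows.append({"variable": var, "category": cat,
                             col_var: cv, **est.as_dict()})
    return pd.DataFrame(rows)


def relative_change(p_start: float, p_end: float) -> float:
    """Signed percent change 100*(p_end - p_start)/p_start.

    Full precision; round to one decimal only at report time.
    """
    if p_start <= 0:
        raise DomainError("relative change requires a positive start value")
    return 100.0 * (p_end - p_start) / p_start
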