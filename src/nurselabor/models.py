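"""Survey-weighted logistic regression with design-based inference.

Implements the repeated cross-sectional modelling strategy: two estimation
samples (underemployed plus health-sector employees; health-sector
employees only), each with three nested covariate sets, for the binary
non-precarious-employment outcome

    logit P(y_j = 1) = b0 + b_sector*Sector_j + b_trim*Trim_j
                       + b_survey*Survey_j + sum_k b_k Z_kj,

where quarter (Trim) and survey year (Survey) enter as categorical factors
and the model always carries the sector-by-year interaction. Level 2 adds
the individual covariates (sex, age band, marital status, university
education, number of jobs); level 3 adds the contextual ones (place of
residence, socioeconomic region).

Estimation is pseudo-maximum likelihood: Newton-Raphson on the weighted
log-likelihood with step-halving; the covariance is the Taylor-linearized
sandwich with stratum/PSU clustering, and all intervals use t critical
values with design df = (#PSUs) - (#strata). Because the model includes the
sector-by-year interaction, the headline sector aOR is the reference-year
sector effect (exp of the ``sector_public`` main-effect coefficient);
goodness of fit is the F-adjusted Hosmer-Lemeshow (Archer-Lemeshow) test,
and adjusted prevalences are predictive margins (weighted average of fitted
probabilities over each cell's observed records) with delta-method SEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import (ConfigurationError, ConvergenceError, DomainError,
                         SeparationError)
from .survey import (EstimateWithCI, SurveyDesign, _proportion_ci,
                     stratified_cluster_variance)

logger = logging.getLogger(__name__)

SAMPLES = ("underemployed_plus_employed", "employed_only")


@dataclass
class ReferenceCategories:
    """Reference levels of the categorical model terms."""

    sector: str = "private"
    sex: str = "male"
    age_band: str = "25_54"
    marital: str = "married_union"
    n_jobs: str = "one"
    residence: str = "rural"
    region: int = 1
    quarter: int = 1
    year: int | None = None  # None = first year observed in the data


@dataclass
class ModelSpec:
    """One of the six sample-by-adjustment model specifications."""

    sample: str
    level: int
    outcome: str = "non_precarious_employment"
    references: ReferenceCategories = field(default_factory=ReferenceCategories)

    def __post_init__(self):
        if self.sample not in SAMPLES:
            raise ConfigurationError(f"unknown sample {self.sample!r}")
        if self.level not in (1, 2, 3):
            raise ConfigurationError(f"unknown model level {self.level!r}")

    @property
    def terms(self) -> tuple:
        base = ("quarter", "year", "sector", "sector:year")
        lvl2 = ("sex", "age_band", "marital", "university", "n_jobs")
        lvl3 = ("residence", "region")
        if self.level == 1:
            return base
        if self.level == 2:
            return base + lvl2
        return base + lvl2 + lvl3


def build_model_spec(sample: str, level: int,
                     references: ReferenceCategories | None = None) -> ModelSpec:
    return ModelSpec(sample=sample, level=level,
                     references=references or ReferenceCategories())


def select_sample(df: pd.DataFrame, sample: str,
                  status_col: str = "labor_status") -> pd.DataFrame:
    if sample == "underemployed_plus_employed":
        return df[df[status_col].isin(["underemployed", "employed_health"])]
    if sample == "employed_only":
        return df[df[status_col] == "employed_health"]
    raise ConfigurationError(f"unknown sample {sample!r}")


def _dummies(series: pd.Series, ref, prefix: str):
    """Deterministically ordered dummy columns, reference level dropped."""
    values = sorted(series.dropna().unique(), key=str)
    cols, names = [], []
    for v in values:
        if str(v) == str(ref):
            continue
        cols.append((series == v).astype(float).to_numpy())
        names.append(f"{prefix}_{v}")
    return cols, names


def design_matrix(df: pd.DataFrame, spec: ModelSpec):
    """Build (X, names) for a model spec. Columns are deterministic."""
    ref = spec.references
    year_ref = ref.year if ref.year is not None else int(df["year"].min())
    cols = [np.ones(len(df))]
    names = ["intercept"]

    c, n = _dummies(df["quarter"], ref.quarter, "quarter")
    cols += c
    names += n
    yc, yn = _dummies(df["year"], year_ref, "year")
    cols += yc
    names += yn
    public = (df["sector"] == "public").astype(float).to_numpy()
    cols.append(public)
    names.append("sector_public")
    for col, name in zip(yc, yn):
        cols.append(public * col)
        names.append(f"sector_public:{name}")

    if spec.level >= 2:
        c, n = _dummies(df["sex"], ref.sex, "sex")
        cols += c
        names += n
        c, n = _dummies(df["age_band"], ref.age_band, "age")
        cols += c
        names += n
        c, n = _dummies(df["marital"], ref.marital, "marital")
        cols += c
        names += n
        cols.append(df["university"].astype(float).to_numpy())
        names.append("university")
        c, n = _dummies(df["n_jobs"], ref.n_jobs, "n_jobs")
        cols += c
        names += n
    if spec.level >= 3:
        c, n = _dummies(df["residence"], ref.residence, "residence")
        cols += c
        names += n
        c, n = _dummies(df["region"], ref.region, "region")
        cols += c
        names += n
    return np.column_stack(cols), names


@dataclass
class ModelFit:
    """A fitted survey-weighted logistic model."""

    spec: ModelSpec | None
    beta: pd.Series
    vcov: pd.DataFrame
    fitted: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    df_design: int
    index: pd.Index
    _X: np.ndarray
    _y: np.ndarray
    _w: np.ndarray
    _strata: np.ndarray
    _psu: np.ndarray

    @property
    def names(self):
        return list(self.beta.index)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=self.beta.index)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Adjusted odds ratios exp(beta) with t(df) confidence bounds."""
        se = self.se()
        tcrit = stats.t.ppf(1 - alpha / 2, max(self.df_design, 1))
        tstat = self.beta / se
        pval = 2 * stats.t.sf(np.abs(tstat), max(self.df_design, 1))
        return pd.DataFrame({
            "term": self.beta.index,
            "beta": self.beta.to_numpy(),
            "se": se.to_numpy(),
            "aor": np.exp(self.beta.to_numpy()),
            "ci_low": np.exp(self.beta.to_numpy() - tcrit * se.to_numpy()),
            "ci_high": np.exp(self.beta.to_numpy() + tcrit * se.to_numpy()),
            "p_value": pval,
        }).reset_index(drop=True)


def adjusted_odds_ratios(fit: ModelFit, term: str,
                         alpha: float = 0.05) -> dict:
    """The aOR of one model term with its confidence interval.

    With the sector-by-year interaction in the model, ``sector_public`` is
    the public-vs-private effect at the reference year.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    table = fit.odds_ratios(alpha=alpha)
    row = table[table["term"] == term]
    if row.empty:
        raise KeyError(f"term {term!r} not in the model "
                       f"(available: {list(table['term'])[:8]} ...)")
    return row.iloc[0].to_dict()


def _check_collinear(X: np.ndarray, names, tol: float = 1e-8):
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(X / scale, mode="r")
    diag = np.abs(np.diag(r))
    bad = [names[j] for j in range(len(names)) if diag[j] < tol * diag.max()]
    if bad:
        raise ConfigurationError(
            f"collinear design columns; drop candidates: {bad}")


def fit_survey_logit(df: pd.DataFrame, spec: ModelSpec, design: SurveyDesign,
                     tol: float = 1e-8, max_iter: int = 50) -> ModelFit:
    """Pseudo-MLE of the survey-weighted logistic model.

    Newton-Raphson with step-halving; convergence when the infinity norm of
    the score (weights normalized to mean one) falls below ``tol * n``.
    Raises :class:`SeparationError` on a degenerate outcome or perfect
    separation and :class:`ConfigurationError` on collinear terms.
    """
    missing = [t for t in ("quarter", "year", "sector") if t not in df.columns]
    if missing:
        raise ConfigurationError(f"missing model columns: {missing}")
    y = df[spec.outcome]
    if y.isna().any():
        raise ConfigurationError(f"missing values in outcome {spec.outcome!r}")
    model_cols = [t for t in spec.terms if ":" not in t]
    if df[model_cols].isna().any().any():
        bad = [c for c in model_cols if df[c].isna().any()]
        raise ConfigurationError(f"missing values in model terms: {bad}")

    X, names = design_matrix(df, spec)
    strata, psu, w_raw = design.layout(df)
    fit = fit_logit_arrays(X, df[spec.outcome].astype(float).to_numpy(),
                           w_raw, strata, psu, names=names, tol=tol,
                           max_iter=max_iter)
    fit.spec = spec
    fit.index = df.index
    return fit


def fit_logit_arrays(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                     strata: np.ndarray, psu: np.ndarray, names=None,
                     tol: float = 1e-8, max_iter: int = 50) -> ModelFit:
    """Array-level survey-weighted logistic fit (core of
    :func:`fit_survey_logit`; also used directly in simulation studies).

    ``psu`` labels must be globally unique (not nested within stratum
    labels); :meth:`SurveyDesign.layout` produces such labels.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if y.min() == y.max():
        raise SeparationError("outcome is constant; model is degenerate")
    _check_collinear(X, names)
    w_raw = np.asarray(w, dtype=float)
    w = w_raw / w_raw.mean()  # point estimates and sandwich are scale-invariant
    n = len(y)

    beta = np.zeros(X.shape[1])
    pbar = np.average(y, weights=w)
    beta[0] = np.log(pbar / (1 - pbar))
    eta = X @ beta
    p = expit(eta)
    ll = float(np.sum(w * (y * np.log(np.clip(p, 1e-12, 1))
                           + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1)))))
    trace = []
    converged = False
    for it in range(max_iter):
        score = X.T @ (w * (y - p))
        trace.append({"iter": it, "loglik": ll,
                      "score_norm": float(np.abs(score).max())})
        if np.abs(score).max() <= tol * n:
            converged = True
            break
        wvar = w * p * (1 - p)
        if wvar.max() < 1e-12:
            raise SeparationError("all fitted probabilities degenerate",
                                  terms=names)
        H = X.T @ (X * wvar[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian: {exc}", terms=names)
        # step-halving on pseudo-log-likelihood decrease
        for half in range(25):
            cand = beta + step
            eta_c = X @ cand
            p_c = expit(eta_c)
            ll_c = float(np.sum(w * (y * np.log(np.clip(p_c, 1e-12, 1))
                                     + (1 - y) * np.log(np.clip(1 - p_c, 1e-12, 1)))))
            if ll_c >= ll - 1e-10:
                break
            step = step / 2
        beta, eta, p, ll = cand, eta_c, p_c, ll_c
        if np.abs(eta).max() > 30 and np.abs(score).max() > tol * n:
            sep_terms = [names[j] for j in np.argsort(-np.abs(beta))[:3]]
            raise SeparationError(
                f"perfect separation suspected (|linear predictor| > 30); "
                f"largest coefficients: {sep_terms}", terms=sep_terms)
    if not converged:
        score = X.T @ (w * (y - p))
        if np.abs(score).max() <= tol * n:
            converged = True
        else:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations",
                trace=trace)
    if np.abs(eta).max() > 30 or np.abs(y - p).max() < 1e-3:
        # saturated or perfectly classified fitted probabilities: separation
        sep_terms = [names[j] for j in np.argsort(-np.abs(beta))[:3]]
        raise SeparationError(
            "perfect separation: fitted probabilities saturate at 0/1; "
            f"largest coefficients: {sep_terms}", terms=sep_terms)

    wvar = w * p * (1 - p)
    H = X.T @ (X * wvar[:, None])
    Hinv = np.linalg.inv(H)
    U = X * (w * (y - p))[:, None]  # per-record score contributions
    G = stratified_cluster_variance(U, strata, psu)
    vcov = Hinv @ G @ Hinv
    dof = len(np.unique(psu)) - len(np.unique(strata))

    return ModelFit(
        spec=None,
        beta=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        fitted=p,
        loglik=ll,
        converged=converged,
        n_obs=n,
        df_design=dof,
        index=pd.RangeIndex(n),
        _X=X, _y=y, _w=w, _strata=strata, _psu=psu,
    )


@dataclass
class ArcherLemeshowResult:
    """F-adjusted Hosmer-Lemeshow test under a complex design."""

    f_statistic: float
    df1: int
    df2: int
    p_value: float
    n_groups: int


def archer_lemeshow_gof(fit: ModelFit, n_groups: int = 10
                        ) -> ArcherLemeshowResult:
    """F-adjusted Hosmer-Lemeshow goodness of fit for a survey logit.

    Records are grouped into ``n_groups`` weighted deciles of fitted
    probability (stable sort; ties broken by record order). The statistic is
    a Wald test that the weighted group-mean residuals are zero, with the
    group means linearized through the estimated coefficients and their
    covariance estimated by stratified between-PSU clustering; the Wald
    quantity W on g-1 groups is referred to F with (g-1, d-g+2) degrees of
    freedom via F = W*(d-g+2)/(d*(g-1)), d being the design df.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    g = int(n_groups)
    p = fit.fitted
    distinct = np.unique(np.round(p, 12))
    if g < 2 or g > len(distinct):
        raise ConfigurationError(
            f"n_groups={g} invalid for {len(distinct)} distinct fitted values")
    d = fit.df_design
    if d - g + 2 <= 0:
        raise ConfigurationError(
            f"design df {d} too small for {g} groups (need df >= g - 1)")

    w, y, X = fit._w, fit._y, fit._X
    order = np.argsort(p, kind="stable")
    cw = np.cumsum(w[order])
    # weighted decile boundaries; searchsorted('left') keeps groups non-empty
    cuts = cw[-1] * np.arange(1, g) / g
    grp_sorted = np.searchsorted(cuts, cw, side="left")
    group = np.empty(len(p), dtype=int)
    group[order] = grp_sorted

    r = y - p
    Wg = np.bincount(group, weights=w, minlength=g)
    if (Wg == 0).any():
        raise ConfigurationError("empty weighted decile group")
    m = np.bincount(group, weights=w * r, minlength=g) / Wg

    # linearization: m_g(beta_hat) ~ m_g - a_g' H^{-1} sum_i psi_i / W_g
    wpq = w * p * (1 - p)
    H = X.T @ (X * wpq[:, None])
    A = np.zeros((g, X.shape[1]))
    for j in range(X.shape[1]):
        A[:, j] = np.bincount(group, weights=wpq * X[:, j], minlength=g)
    C = np.linalg.solve(H.T, A.T).T  # A H^{-1}, shape (g, k)

    psi = X * (w * r)[:, None]
    Z = np.zeros((len(p), g - 1))
    for gi in range(g - 1):
        direct = np.where(group == gi, w * r, 0.0)
        Z[:, gi] = (direct - psi @ C[gi]) / Wg[gi]
    V = stratified_cluster_variance(Z, fit._strata, fit._psu)
    mvec = m[: g - 1]
    try:
        wald = float(mvec @ np.linalg.solve(V, mvec))
    except np.linalg.LinAlgError:
        wald = float(mvec @ np.linalg.pinv(V) @ mvec)
    f_stat = wald * (d - g + 2) / (d * (g - 1))
    p_value = float(stats.f.sf(f_stat, g - 1, d - g + 2))
    return ArcherLemeshowResult(f_statistic=float(f_stat), df1=g - 1,
                                df2=d - g + 2, p_value=p_value, n_groups=g)


def adjusted_prevalence(fit: ModelFit, data: pd.DataFrame,
                        by=("period", "region"), alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Predictive margins (adjusted prevalences) over observed records.

    For each cell of ``by`` (for the headline use: survey period by
    socioeconomic region, from the most comprehensive model), the margin is
    the weighted mean of fitted probabilities over the cell's records; its
    SE propagates the coefficient covariance by the delta method. Margins
    are invariant to rescaling all weights. Empty cells are omitted.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge")
    by = list(by)
    data = data.loc[fit.index]
    X, w, p = fit._X, fit._w, fit.fitted
    V = fit.vcov.to_numpy()
    tcrit_df = max(fit.df_design, 1)

    rows = []
    grouped = data.groupby(by, sort=True, observed=True)
    for keys, block in grouped:
        if not isinstance(keys, tuple):
            keys = (keys,)
        idx = data.index.get_indexer(block.index)
        Wc = w[idx].sum()
        m = float(np.sum(w[idx] * p[idx]) / Wc)
        grad = (w[idx] * p[idx] * (1 - p[idx])) @ X[idx] / Wc
        var = float(grad @ V @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        ci_low, ci_high = _proportion_ci(m, se, tcrit_df, len(idx), alpha,
                                         "logit")
        est = EstimateWithCI(estimate=m, se=se, ci_low=ci_low,
                             ci_high=ci_high, n_unweighted=len(idx),
                             n_weighted=float(Wc))
        rows.append({**dict(zip(by, keys)), **est.as_dict()})
    return pd.DataFrame(rows)
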