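# Methods

## The problem and the estimands

`nurselabor` analyzes the performance of a professional (nursing) labor
market from repeated cross-sections of a quarterly, rotating-panel
household labor-force survey. Performance is read off four indicators for
economically active nurses:

* **unemployment** — not working for pay though available and wanting to
  work;
* **underemployment** — in the professional-market sense: a trained nurse
  working outside the health sector;
* **employment** — working in the health sector;
* **non-precarious employment** — the headline outcome: employed in the
  health sector with an additive precariousness score of exactly zero.

The precariousness score is a non-weighted sum of five dichotomous adverse
conditions (1 = adverse):

| component | adverse when | default threshold |
|---|---|---|
| salary | income ≤ 2 × minimum wage (inclusive) | `salary_mw_cut = 2.0` |
| workday | weekly hours < 34 or > 48 | `hours_low = 34`, `hours_high = 48` |
| contract | no written contract | — |
| benefits | no social benefit at all | — |
| social security | no social-security health-service access | — |

so each worker scores 0–5. The boundary conventions are deliberate: the
salary rule is inclusive ("up to two times" the minimum wage is adverse)
and the 34–48 h band inclusive is unflagged. A two-level summary
("non- or low-precarious" vs "highly precarious") cuts the score at
`high_cut`; the source analyses do not state the cut behind their
two-level series, so the package defaults to 3 (a majority of the five
components adverse) and exposes it in configuration.

Scores are computed for underemployed workers too, with the same five
rules, because the descriptive cross-tabulations distinguish precarious
from non-precarious underemployment. The binary outcome used in the
regressions is 1 only for health-sector employees with score 0; it is 0
for every other worker and undefined (excluded) for the unemployed.

## Sample construction

From schema-conforming person-quarter records the analytic sample keeps,
in order: (1) first-visit households only — in a 5-visit rotating panel
this removes the ~80% quarterly redundancy and the attendant seasonality
of repeated observation units; (2) economically active persons whose
occupation code is in the configured nurse catalogue; (3) records with
complete information on the variables of interest. Completeness is
interpreted per applicability: the five employment fields are required of
working records only, so unemployed nurses (for whom those questions do
not arise) are never excluded for lacking them. Every stage is counted in
a `SampleAudit`; the pipeline reports its own audit rather than forcing
any externally printed count.

Period bins follow the federal administrations covering the study window:
2005–2006, 2007–2009, 2010–2012, 2013–2015, 2016–2018, 2019. They
partition 2005–2019; years outside the window are a domain error.

## Design-based estimation

All descriptive estimates are ratio estimators `p = Σ w d y / Σ w d`
under a stratified two-stage design (stratum → PSU → person weight `w`),
with Taylor-linearized between-PSU variance

    V = Σ_h n_h/(n_h−1) Σ_j (t_hj − t̄_h)² ,

where `t_hj` sums the linearized contributions
`u_i = w_i d_i (y_i − p)/Σ w d` over PSU `j` of stratum `h`. Domain
(subpopulation) estimation keeps the full design: out-of-domain records
contribute zeros but their strata and PSUs stay in the variance, which is
the design-consistent treatment. Confidence intervals for proportions are
logit-transformed Wald intervals with a t critical value at
`df = #PSUs − #strata` (plain Wald available as an option); degenerate
estimates of exactly 0 or 1 get a one-sided exact-style bound
`1 − (α/2)^{1/n}`. Strata with a single PSU are an error by default; an
opt-in rule pools all single-PSU strata into one synthetic stratum for
real data. Estimates and SEs are invariant to rescaling all weights by a
positive constant.

## Survey-weighted logistic models

Two estimation samples (underemployed + health-sector employees;
health-sector employees only) each get three nested specifications of

    logit P(y=1) = β0 + β_sector·Sector + β_trim·Trim + β_survey·Survey
                   + Σ_k β_k Z_k ,

with quarter and survey year as categorical factors and the full
sector-by-year interaction always present. Level 2 adds sex, age band,
marital status, university education and number of jobs; level 3 adds
place of residence and socioeconomic region. Reference categories
(private sector, male, age 25–54, married/union, one job, rural,
poorest region, first quarter, first observed year) are configurable.

Fitting is pseudo-maximum likelihood: Newton–Raphson on the weighted
log-likelihood with step-halving on any decrease, convergence when the
infinity norm of the score falls below `1e-8 × n` after normalizing
weights to mean one (the point estimates and the sandwich are invariant
to weight scale, so the normalization is purely numerical). Degenerate
outcomes, perfect separation (saturated or perfectly classified fitted
probabilities) and collinear design columns raise typed errors naming the
offending terms. The covariance is the linearized sandwich
`H⁻¹ G H⁻¹` with `G` the stratified between-PSU covariance of the score
contributions; all intervals and p-values use t(df), df = PSUs − strata.

Because of the sector-by-year interaction there is no single sector
coefficient; the package reports `sector_public` — the public-vs-private
effect at the reference year — as the headline adjusted odds ratio. This
is a parameterization choice the source tables do not pin down, and it is
configurable through the reference year.

**Goodness of fit** is the F-adjusted Hosmer–Lemeshow (Archer–Lemeshow)
test: records are cut into 10 weighted deciles of fitted probability
(stable sort, ties by record order); the weighted mean residual per
decile is linearized through the estimated coefficients
(`z_i = [w_i 1{i∈g}(y_i−p_i) − a_g' H⁻¹ w_i x_i (y_i−p_i)]/W_g`), its
covariance estimated with the same stratified clustering, and the Wald
quantity on the first g−1 group means is referred to
F(g−1, d−g+2) via `F = W (d−g+2)/(d (g−1))`. The correction term for
estimated coefficients matters: without it the test is anticonservative.
Simulation (500 replicates, correctly specified weighted logit) puts the
empirical size at ≈0.04–0.07 at α = 0.05, and power against a strong
omitted quadratic at n = 10,000 is ≈1.

**Adjusted prevalences** are predictive margins: for each survey-period ×
region cell, the weighted mean of fitted probabilities over the cell's
observed records (average marginal prediction, not prediction at means),
with delta-method SEs through the coefficient covariance and logit-scale
t intervals. An intercept-only model reproduces the overall weighted
prevalence in every cell, and margins are weight-scale invariant.

## The synthetic survey and what it does (not) emulate

The generator emulates the occupation-screened extract of the survey, not
the full population survey — hence a high default `nurse_fraction` (0.5).
Households enter in quarterly cohorts and carry `visit_number` 1–5, so
exactly ~20% of any quarter's households are first visits; household
members are redrawn each quarter (no longitudinal linkage — analysis uses
first visits only, and longitudinal linkage is out of scope). Design
structure: 32 strata × 6 PSUs (echoing state-level representativity;
purely conventional), log-normal person weights with mean 250 — sized so
that ~19,000 analytic records expand to a population of several million,
the scale of the real study (19,311 records, N = 4,816,930).

Defaults define the study conditions: 60 quarters (2005–2019),
1,875 households/quarter (≈22,000 economically active first-visit nurses;
≈19,000 after the 12% incomplete-record exclusion, matching the published
21,854 → 19,311 attrition), per-period labor-status probabilities that
reproduce the published endpoints (underemployment 26.7% → 33.7%,
health-sector employment 68.6% → 61.4%, unemployment ≈5% flat), and
covariate distributions shaped like the published descriptive table
(91% female, 75% aged 25–54, 45% university-educated, mostly metropolitan).

Each precariousness component is drawn from an independent logistic model
for the *non*-precarity propensity with intercept, public-sector, per-year
trend, university and male terms. Independence given covariates is a
deliberate design choice: it makes `P(score = 0 | x) = Π_k expit(η_k(x))`
factorizable, so ground truth is computable by Monte-Carlo integration
(`expected_truth`, ≥10⁵ draws). Default coefficients put the zero-score
probability among health-sector employees at ≈0.60 (public) and ≈0.31
(private) in 2005, deteriorating over time — the published gradient.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: correlation among the five components (real
adverse conditions cluster strongly, so the generator understates the
heavy score-3+ tail that the published two-level series show, even though
the zero-score outcome is calibrated); true sampling-frame structure,
nonresponse and calibration weighting; within-household and within-PSU
outcome correlation; measurement/recall error; and the actual occupation
catalogue (a synthetic two-code set stands in).

For parameter-recovery studies, `single_component_params` degenerates
four components to "never precarious" so the zero-score outcome is
*exactly* logistic with a known sector log-odds ratio (default log 7) —
the conditional public-vs-private odds ratio is then exp(β) in closed
form.

## Validation protocol and problem sizes

* Estimator oracle: equal weights + one-PSU-per-record reduce the
  pseudo-MLE to ordinary maximum likelihood (statsmodels GLM, 1e-6 on a
  200-record fixture) and the linearized variance to `p(1−p)/(n−1)`
  (1e-10); an 8-record, 2-strata × 2-PSU table is checked against the
  hand-worked value 5/576.
* Sector-effect recovery: replicates of ≈20,000 health-sector employees
  from the single-component process; the t-based 95% CI for the
  reference-year sector coefficient is required to cover log 7 in ≥93% of
  replicates with |bias| < 0.05. The test suite uses 600 replicates so the
  binomial noise of the coverage estimate (SE ≈ 0.9 points) is small
  against the 2-point margin below the nominal 95%; the reproducibility
  script uses 200 under its caller's seed.
* GOF calibration: 500 correctly specified replicates (n = 2,000) for
  size, 150 misspecified replicates (n = 10,000, omitted quadratic) for
  power.
* CI coverage of the proportion estimator: 1,000 SRS replicates
  (n = 400, p = 0.3), 95% ± 2%.

All randomness flows from explicit integer seeds; replicate seeds are
spawned from one master generator, and regenerating with the same
parameters is byte-identical.

## Known limitations

* The component-independence assumption (above) limits realism of the
  score distribution's upper tail.
* Real-data aORs are not reproducible without the real survey microdata;
  the package validates against synthetic ground truth instead.
* Single-PSU strata are handled by pooling, a blunt (if common) rule.
* The Archer–Lemeshow denominator df `d − g + 2` requires a design with
  at least `g − 1` more PSUs than strata.
* Replicate-weight variance (BRR/jackknife), calibration weighting,
  multilevel models and longitudinal linkage are out of scope.
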