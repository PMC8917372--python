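"""End-to-end orchestration: simulate -> classify -> score -> estimate ->
fit -> report, as one reproducible run.

A single :class:`RunConfig` (plain YAML) drives everything; every emitted
file carries a ``# config_hash=... seed=...`` comment header so any output
can be traced to the exact configuration that produced it. All stored
values are full precision; rounding to one decimal happens only in
:func:`render_text_tables`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import schema as sch
from .cohort import (DEFAULT_REQUIRED_FIELDS, add_period_column,
                     build_analytic_sample, classify_labor_status_frame)
from .exceptions import ConfigurationError
from .models import (ReferenceCategories, SAMPLES, archer_lemeshow_gof,
                     build_model_spec, fit_survey_logit, select_sample)
from .precarity import PrecarityConfig, add_precarity_columns, five_way_status
from .survey import (SurveyDesign, labor_status_distribution, relative_change,
                     weighted_crosstab, weighted_proportion)
from .synthetic import SimulationParams, generate_microdata

logger = logging.getLogger(__name__)

TABLE1_ROW_VARS = ("sex", "age_band", "marital", "university", "sector",
                   "n_jobs", "residence", "region")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with no hidden defaults at run time
    (the effective configuration is logged and hashed into every output)."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    input_path: str | None = None  # when set, skip simulation and read this
    nurse_codes: frozenset = sch.NURSE_CODES
    required_fields: tuple = DEFAULT_REQUIRED_FIELDS
    precarity: PrecarityConfig = field(default_factory=PrecarityConfig)
    design: SurveyDesign = field(default_factory=SurveyDesign)
    references: ReferenceCategories = field(default_factory=ReferenceCategories)
    gof_groups: int = 10
    out_dir: str = "results"
    seed: int | None = None  # overrides simulation.seed when set
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        # hash the scientific configuration, not where it is written/logged
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @property
    def effective_seed(self) -> int:
        return self.simulation.seed if self.seed is None else int(self.seed)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set, tuple)):
        return sorted(map(str, obj)) if isinstance(obj, (frozenset, set)) \
            else [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    sim = raw.get("simulation", {})
    if sim:
        known = {f.name for f in dataclasses.fields(SimulationParams)}
        unknown = set(sim) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        if "quarters" in sim:
            sim["quarters"] = [tuple(q) for q in sim["quarters"]]
        cfg.simulation = dataclasses.replace(cfg.simulation, **sim)
    if "precarity" in raw:
        cfg.precarity = dataclasses.replace(cfg.precarity, **raw["precarity"])
    if "design" in raw:
        cfg.design = dataclasses.replace(cfg.design, **raw["design"])
    if "references" in raw:
        cfg.references = dataclasses.replace(cfg.references, **raw["references"])
    for key in ("input_path", "out_dir", "seed", "log_level", "gof_groups"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "nurse_codes" in raw:
        cfg.nurse_codes = frozenset(raw["nurse_codes"])
    if "required_fields" in raw:
        cfg.required_fields = tuple(raw["required_fields"])
    return cfg


def setup_logging(config: RunConfig, out_dir: Path) -> None:
    handlers = [logging.StreamHandler(sys.stderr),
                logging.FileHandler(out_dir / "run.log")]
    logging.basicConfig(level=getattr(logging, config.log_level.upper()),
                        handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _write(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns the in-memory results: audit, fig1/table1/fig2-style estimate
    tables, the six model fits with GOF, the adjusted-prevalence tables and
    the headline relative-change summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(config, out_dir)
    meta = {"config_hash": config.config_hash(), "seed": config.effective_seed}
    logger.info("run config: %s", json.dumps(_as_jsonable(config), default=str))

    stage = "simulate/load"
    try:
        if config.input_path:
            micro = sch.read_microdata(config.input_path)
        else:
            sim = dataclasses.replace(config.simulation,
                                      seed=config.effective_seed)
            micro = generate_microdata(sim)
            sch.write_microdata(micro, out_dir / "microdata.csv", meta)
        logger.info("microdata: %d records", len(micro))

        stage = "classify"
        sample, audit = build_analytic_sample(
            micro, nurse_codes=config.nurse_codes,
            required_fields=config.required_fields)
        sample = classify_labor_status_frame(sample)
        sample = add_period_column(sample)
        audit_df = pd.DataFrame([audit.as_dict()])
        _write(audit_df, out_dir / "sample_audit.csv", meta)
        (out_dir / "sample_audit.txt").write_text(
            "\n".join(f"{k}: {v}" for k, v in meta.items())
            + "\n" + "\n".join(f"{k}: {v}" for k, v in audit.as_dict().items())
            + "\n")
        logger.info("analytic sample: %s", audit.as_dict())

        stage = "score"
        sample = add_precarity_columns(sample, config.precarity)
        sample = five_way_status(sample)
        # schema columns plus the classification/scoring columns added above
        _write(sample, out_dir / "analytic_sample.csv", meta)

        stage = "estimate"
        design = config.design
        fig1 = labor_status_distribution(sample, design)
        _write(fig1, out_dir / "fig1_labor_status_by_period.csv", meta)
        table1 = weighted_crosstab(sample, TABLE1_ROW_VARS, "status5", design)
        _write(table1, out_dir / "table1_crosstab.csv", meta)
        fig2 = precarity_level_series(sample, design)
        _write(fig2, out_dir / "fig2_precarity_by_sector_period.csv", meta)

        stage = "fit"
        fits, table2_rows, margins = {}, [], {}
        for samp in SAMPLES:
            sub = select_sample(sample, samp)
            for level in (1, 2, 3):
                spec = build_model_spec(samp, level, config.references)
                fit = fit_survey_logit(sub, spec, design)
                gof = archer_lemeshow_gof(fit, n_groups=config.gof_groups)
                fits[(samp, level)] = (fit, gof)
                aor = fit.odds_ratios()
                aor.insert(0, "sample", samp)
                aor.insert(1, "level", level)
                aor["n_obs"] = fit.n_obs
                aor["gof_f"] = gof.f_statistic
                aor["gof_p"] = gof.p_value
                table2_rows.append(aor)
                logger.info("model %s level %d: n=%d loglik=%.2f gof_p=%.3f",
                            samp, level, fit.n_obs, fit.loglik, gof.p_value)
            from .models import adjusted_prevalence
            fit3, _ = fits[(samp, 3)]
            marg = adjusted_prevalence(fit3, sub, by=["period", "region"])
            marg.insert(0, "sample", samp)
            margins[samp] = marg
        table2 = pd.concat(table2_rows, ignore_index=True)
        _write(table2, out_dir / "table2_model_fits.csv", meta)
        fig3 = pd.concat(margins.values(), ignore_index=True)
        _write(fig3, out_dir / "fig3_adjusted_prevalence.csv", meta)

        stage = "report"
        changes = headline_changes(fig1, fig2)
        _write(changes, out_dir / "headline_relative_changes.csv", meta)
        (out_dir / "headline_relative_changes.txt").write_text(
            render_text_tables(changes, meta))
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"audit": audit, "sample": sample, "fig1": fig1, "table1": table1,
            "fig2": fig2, "table2": table2, "fits": fits, "fig3": fig3,
            "changes": changes, "meta": meta}


def precarity_level_series(sample: pd.DataFrame, design: SurveyDesign
                           ) -> pd.DataFrame:
    """Share of workers at each precariousness level, by sector and period."""
    workers = sample[sample["labor_status"] == "employed_health"]
    rows = []
    for sector in ("private", "public"):
        for period in sorted(workers["period"].dropna().unique()):
            dom = (workers["sector"] == sector) & (workers["period"] == period)
            if not dom.any():
                logger.warning("no %s workers in %s; omitted", sector, period)
                continue
            for lvl in ("non_or_low", "high"):
                est = weighted_proportion(
                    workers, (workers["level"] == lvl).astype(float),
                    design, domain=dom)
                rows.append({"sector": sector, "period": period, "level": lvl,
                             **est.as_dict()})
    return pd.DataFrame(rows)


def headline_changes(fig1: pd.DataFrame, fig2: pd.DataFrame) -> pd.DataFrame:
    """First-to-last-period relative changes of the headline series."""
    first, last = fig1["period"].min(), fig1["period"].max()

    def share(df, **sel):
        m = pd.Series(True, index=df.index)
        for k, v in sel.items():
            m &= df[k] == v
        return 100.0 * float(df[m]["estimate"].iloc[0])

    rows = []
    for status in ("underemployed", "employed_health", "unemployed"):
        p0 = share(fig1, period=first, status=status)
        p1 = share(fig1, period=last, status=status)
        rows.append({"series": f"{status}_share", "start_period": first,
                     "end_period": last, "start_pct": p0, "end_pct": p1,
                     "relative_change_pct": relative_change(p0, p1)})
    for sector in ("private", "public"):
        p0 = share(fig2, sector=sector, period=first, level="non_or_low")
        p1 = share(fig2, sector=sector, period=last, level="non_or_low")
        rows.append({"series": f"{sector}_non_or_low_precarious_share",
                     "start_period": first, "end_period": last,
                     "start_pct": p0, "end_pct": p1,
                     "relative_change_pct": relative_change(p0, p1)})
    return pd.DataFrame(rows)


def render_tables(results: dict, fmt: str, out_dir) -> list:
    """Write every tabular result as CSV or human-readable text.

    ``results`` is the mapping returned by :func:`run_pipeline` (or any
    subset of its DataFrame entries). Text rendering rounds percentages to
    one decimal; stored CSV values stay full precision.
    """
    if fmt not in ("csv", "text"):
        raise ConfigurationError(f"unknown render format {fmt!r}")
    tables = {k: v for k, v in results.items()
              if isinstance(v, pd.DataFrame) and not v.empty}
    if not tables:
        raise ConfigurationError("no tabular results to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = results.get("meta", {})
    written = []
    for name, df in tables.items():
        if fmt == "csv":
            path = out_dir / f"{name}.csv"
            _write(df, path, meta)
        else:
            path = out_dir / f"{name}.txt"
            path.write_text(render_text_tables(df, meta))
        written.append(path)
    return written


def render_text_tables(df: pd.DataFrame, meta: dict) -> str:
    """Human-readable rendering; percentages rounded to one decimal."""
    out = [f"# {k}={v}" for k, v in meta.items()]
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].round(1)
    out.append(show.to_string(index=False))
    return "\n".join(out) + "\n"
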