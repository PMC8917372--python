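"""Columnar schema for person-quarter labor-force microdata.

One row is one surveyed person in one quarter of a rotating-panel household
labor-force survey (ENOE-like). The schema carries the survey-design
variables (stratum, primary sampling unit, expansion weight, visit number),
the occupation code, the employment fields needed for the five precariousness
indicators, and the sociodemographic covariates used in the regression
models. All files are plain delimited text (CSV) with this header.

Boolean-like fields are stored as 0/1 (nullable ``Int8``): ``1`` means the
condition holds. Fields that do not apply to a record (employment conditions
of a person who is not working) are left empty.
"""

from __future__ import annotations

import io
from collections import OrderedDict

import pandas as pd

from .exceptions import SchemaError

# -- categorical vocabularies -------------------------------------------------

SECTORS = ("public", "private", "none")
SEXES = ("female", "male")
AGE_BANDS = ("24_or_less", "25_54", "55_plus")
MARITALS = ("married_union", "single", "divorced_widowed")
N_JOBS = ("one", "two_plus")
RESIDENCES = ("rural", "semi_urban", "urban", "metropolitan")
REGIONS = (1, 2, 3, 4, 5, 6)  # 1 = poorest ... 6 = wealthiest

#: Synthetic nurse occupation codes shipped with the package. The real
#: occupation catalogue changed over 2005-2019, so real-data runs must supply
#: their own code set.
NURSE_CODES = frozenset({"N111", "N112"})

#: Employment fields that feed the five precariousness indicators. They are
#: defined only for working records; completeness checks apply them to
#: working records only.
EMPLOYMENT_FIELDS = (
    "income_mw",
    "weekly_hours",
    "written_contract",
    "any_social_benefit",
    "ss_health_access",
)

#: column -> (pandas dtype, allowed values or None, description)
SCHEMA: "OrderedDict[str, tuple]" = OrderedDict(
    [
        ("household_id", ("string", None, "household identifier")),
        ("person_id", ("string", None, "person identifier (unique per row)")),
        ("year", ("int64", None, "survey year")),
        ("quarter", ("int64", (1, 2, 3, 4), "survey quarter")),
        ("visit_number", ("int64", (1, 2, 3, 4, 5), "rotating-panel visit 1-5")),
        ("stratum_id", ("int64", None, "design stratum")),
        ("psu_id", ("int64", None, "primary sampling unit within stratum")),
        ("weight", ("float64", None, "expansion factor (persons represented)")),
        ("occupation_code", ("string", None, "occupation catalogue code")),
        ("economically_active", ("Int8", (0, 1), "in the labor force")),
        ("working", ("Int8", (0, 1), "worked for pay")),
        ("available_and_seeking", ("Int8", (0, 1), "available and desires to work")),
        ("sector", ("string", SECTORS, "labor sector; 'none' if not working")),
        ("in_health_sector", ("Int8", (0, 1), "employed in the health sector")),
        ("weekly_hours", ("float64", None, "usual weekly working hours")),
        ("income_mw", ("float64", None, "income as a multiple of the minimum wage")),
        ("written_contract", ("Int8", (0, 1), "has a written contract")),
        ("any_social_benefit", ("Int8", (0, 1), "has at least one social benefit")),
        ("ss_health_access", ("Int8", (0, 1), "social-security health-service access")),
        ("sex", ("string", SEXES, "sex")),
        ("age_band", ("string", AGE_BANDS, "age band in years")),
        ("marital", ("string", MARITALS, "marital status")),
        ("university", ("Int8", (0, 1), "bachelor's or other university degree")),
        ("n_jobs", ("string", N_JOBS, "number of jobs")),
        ("residence", ("string", RESIDENCES, "place of residence")),
        ("region", ("Int8", REGIONS, "socioeconomic region, 1 poorest - 6 wealthiest")),
    ]
)

COLUMNS = tuple(SCHEMA)

_DTYPES = {col: spec[0] for col, spec in SCHEMA.items()}


def write_schema_file(path) -> None:
    """Write the machine-readable schema (column, dtype, allowed, description)."""
    rows = [
        {
            "column": col,
            "dtype": dtype,
            "allowed": "" if allowed is None else "|".join(str(a) for a in allowed),
            "description": desc,
        }
        for col, (dtype, allowed, desc) in SCHEMA.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_nurse_codes(path, codes=NURSE_CODES) -> None:
    with open(path, "w") as fh:
        for code in sorted(codes):
            fh.write(f"{code}\n")


def read_nurse_codes(path) -> frozenset:
    with open(path) as fh:
        codes = {line.strip() for line in fh if line.strip()}
    return frozenset(codes)


def coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    """Cast a raw frame to the canonical dtypes, in schema column order."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing schema columns: {missing}")
    out = df.loc[:, list(COLUMNS)].copy()
    for col, dtype in _DTYPES.items():
        out[col] = out[col].astype(dtype)
    return out


def validate_microdata(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` on structural violations.

    Checks columns, dtype-coercibility, allowed categorical values, positive
    weights and the working/sector consistency rule (non-working records
    carry sector 'none' and are not in the health sector).
    """
    df = coerce_dtypes(df)
    for col, (_, allowed, _) in SCHEMA.items():
        if allowed is None:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin(list(allowed))
        if bad.any():
            raise SchemaError(
                f"column {col!r} has values outside {allowed}: "
                f"{sorted(vals[bad].unique().tolist())[:5]}"
            )
    if (df["weight"] <= 0).any():
        raise SchemaError("weights must be strictly positive")
    not_working = df["working"].fillna(0) == 0
    if (df.loc[not_working, "sector"] != "none").any():
        raise SchemaError("non-working records must have sector == 'none'")
    if (df.loc[not_working, "in_health_sector"].fillna(0) == 1).any():
        raise SchemaError("non-working records cannot be in the health sector")


def write_microdata(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write microdata as CSV, with optional ``# key=value`` comment header."""
    df = coerce_dtypes(df)
    buf = io.StringIO()
    if metadata:
        for key, value in metadata.items():
            buf.write(f"# {key}={value}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_microdata(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"occupation_code": "string"})
    return coerce_dtypes(df)
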