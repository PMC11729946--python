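"""Administrative-record data model, CSV IO, exclusions and person-year views.

The pipeline consumes four linked person-level tables (a fifth source, death
registrations, is folded into ``persons.death_date``):

``persons``
    one row per resident: demographics, socio-economic markers, death date;
``conditions``
    chronic-disease registry diagnoses with first-diagnosis dates;
``programs``
    program claims/referrals used as need proxies (nursing-home admission for
    frailty, palliative referral, transitional-care enrollment);
``encounters``
    healthcare contacts with setting, date, gross unsubsidized charges, bed
    days and an ICU flag.

All tables are UTF-8 CSV with ISO-8601 dates, one row per record.
``assemble_person_year`` turns them into the per-person calendar-year feature
rows the classifier consumes: event flags are computed from events dated
within the index year, while condition history persists (any diagnosis dated
on or before Dec 31 of the index year counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .registry import COUNTING_CATEGORIES, DEFAULT_REGISTRY, specialist_care_codes

logger = logging.getLogger(__name__)

GENDERS = ("male", "female")
ETHNICITIES = ("Chinese", "Malay", "Indian", "Others")
HOUSING_TYPES = ("rental_public", "nonrental_public", "private")
CHAS_TIERS = ("none", "orange", "blue")
REGIONS = ("Central", "Western", "Eastern")
PROGRAMS = (
    "nursing_home_admission",
    "palliative_referral",
    "transitional_care_enrollment",
    "pediatric_longterm_program",
)
SETTINGS = (
    "inpatient_acute",
    "day_surgery",
    "emergency",
    "specialist_outpatient",
    "polyclinic",
    "chas_gp",
)
#: Settings that carry bed days.
INPATIENT_SETTINGS = ("inpatient_acute",)

#: Maximum plausible age; older persons are presumed to have a missing death
#: record and are excluded from the base population.
MAX_AGE = 110

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "persons": (
        "person_id",
        "birth_year",
        "gender",
        "ethnicity",
        "housing",
        "chas_tier",
        "pioneer_generation",
        "lives_alone",
        "region",
        "death_date",
    ),
    "conditions": ("person_id", "condition_code", "first_diagnosis_date", "category"),
    "programs": ("person_id", "program", "event_date"),
    "encounters": (
        "person_id",
        "setting",
        "encounter_date",
        "charges",
        "bed_days",
        "icu_flag",
        "specialty",
    ),
}

_DATE_COLUMNS = {
    "persons": ("death_date",),
    "conditions": ("first_diagnosis_date",),
    "programs": ("event_date",),
    "encounters": ("encounter_date",),
}

_BOOL_COLUMNS = {
    "persons": ("pioneer_generation", "lives_alone"),
    "encounters": ("icu_flag",),
}

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no", ""}

EXCLUSION_REASONS = ("ethnicity_missing", "age_above_110", "not_alive_in_year")


class SchemaError(ValueError):
    """A table is missing required columns or has an unknown name."""


class RowParseError(ValueError):
    """One or more rows could not be parsed; message carries line numbers."""


@dataclass
class BasePopulation:
    """Residents passing exclusions for an index year, with removal counts."""

    year: int
    persons: pd.DataFrame
    excluded_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.persons)


def _parse_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    s = series.astype("string").fillna("").str.strip().str.lower()
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise RowParseError(
            f"{table}.{column}: {int(bad.sum())} unparseable boolean value(s) "
            f"at line(s) {lines[:10]}"
        )
    return s.isin(_TRUE)


def _parse_dates(series: pd.Series, table: str, column: str) -> pd.Series:
    raw = series.astype("string").fillna("").str.strip()
    parsed = pd.to_datetime(raw.replace("", pd.NA), format="ISO8601", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise RowParseError(
            f"{table}.{column}: {int(bad.sum())} unparseable date(s) "
            f"at line(s) {lines[:10]}"
        )
    return parsed


def read_tables(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read the administrative CSV tables into typed DataFrames.

    Parameters
    ----------
    paths
        Mapping from table name (a key of :data:`TABLE_SCHEMAS`) to CSV path.

    Raises
    ------
    SchemaError
        Unknown table name or missing required column.
    RowParseError
        Unparseable dates or booleans, reported with 1-based line numbers.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if name not in TABLE_SCHEMAS:
            raise SchemaError(f"unknown table {name!r}")
        df = pd.read_csv(path, dtype="string", keep_default_na=False)
        missing = [c for c in TABLE_SCHEMAS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing required column(s) {missing}")
        for col in _DATE_COLUMNS.get(name, ()):
            df[col] = _parse_dates(df[col], name, col)
        for col in _BOOL_COLUMNS.get(name, ()):
            df[col] = _parse_bool(df[col], name, col)
        if name == "persons":
            df["birth_year"] = df["birth_year"].astype(int)
            df["ethnicity"] = df["ethnicity"].replace("", pd.NA)
        if name == "encounters":
            df["charges"] = df["charges"].astype(float)
            df["bed_days"] = df["bed_days"].astype(int)
        tables[name] = df
    return tables


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write tables as UTF-8 CSV with ISO dates; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        if name not in TABLE_SCHEMAS:
            raise SchemaError(f"unknown table {name!r}")
        df = df.copy()
        for col in _DATE_COLUMNS.get(name, ()):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


def apply_exclusions(persons: pd.DataFrame, year: int) -> BasePopulation:
    """Apply the base-population exclusion criteria for an index year.

    Retains persons with known ethnicity, age (attained in the index year)
    at most 110, and alive at some point during the index year.  Each removed
    person is attributed to the first matching reason in the fixed order
    ethnicity-missing, age > 110, not-alive-in-year, so the counts partition
    the removals.  Idempotent.
    """
    age = year - persons["birth_year"]
    eth_missing = persons["ethnicity"].isna()
    too_old = age > MAX_AGE
    death = pd.to_datetime(persons["death_date"])
    dead_before = death.notna() & (death < pd.Timestamp(year, 1, 1))
    not_alive = dead_before | (persons["birth_year"] > year)

    reason = np.select(
        [eth_missing, too_old, not_alive],
        EXCLUSION_REASONS,
        default="",
    )
    counts = {r: int((reason == r).sum()) for r in EXCLUSION_REASONS}
    kept = persons.loc[reason == ""].reset_index(drop=True)
    return BasePopulation(year=year, persons=kept, excluded_counts=counts)


def _flag_in_year(events: pd.DataFrame, date_col: str, year: int, mask=None) -> pd.Index:
    """person_ids with at least one event dated inside the index year."""
    in_year = events[date_col].dt.year == year
    if mask is not None:
        in_year &= mask
    return pd.Index(events.loc[in_year, "person_id"].unique())


def assemble_person_year(
    base: BasePopulation,
    conditions: pd.DataFrame,
    programs: pd.DataFrame,
    encounters: pd.DataFrame | None = None,
    registry: Mapping[str, str] | None = None,
    specialist_codes: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Build one classification-feature row per person in the base population.

    Program flags (frailty, palliative, transitional) come from events dated
    within the index year; condition flags use the full diagnosis history up
    to the end of the index year.  Records for persons outside the base
    population are ignored (counted in a warning log line).

    Returns a DataFrame with one row per person: identifiers, age / age band,
    clinical flags, chronic-condition counts, risk-factor flags and the
    demographic passthrough columns.
    """
    year = base.year
    persons = base.persons
    registry = dict(DEFAULT_REGISTRY if registry is None else registry)
    if specialist_codes is None:
        specialist_codes = specialist_care_codes(registry)

    known = pd.Index(persons["person_id"])
    for name, df in (("conditions", conditions), ("programs", programs)):
        unknown = (~df["person_id"].isin(known)).sum()
        if unknown:
            logger.warning("%s: %d record(s) for persons outside base population", name, unknown)
    if encounters is not None:
        unknown = int((~encounters["person_id"].isin(known)).sum())
        if unknown:
            logger.warning("encounters: %d record(s) for unknown persons", unknown)

    out = persons[
        [
            "person_id",
            "gender",
            "ethnicity",
            "housing",
            "chas_tier",
            "pioneer_generation",
            "lives_alone",
            "region",
        ]
    ].copy()
    out.insert(1, "year", year)
    age = (year - persons["birth_year"]).to_numpy()
    out.insert(2, "age", age)
    out.insert(
        3,
        "age_band",
        np.select([age <= 18, age >= 65], ["child", "senior"], default="adult"),
    )

    death = pd.to_datetime(persons["death_date"])
    out["died_in_year"] = (death.dt.year == year).fillna(False).to_numpy()

    prog = programs.loc[programs["person_id"].isin(known)]
    by_program = {
        p: _flag_in_year(prog, "event_date", year, prog["program"] == p) for p in PROGRAMS
    }
    out["palliative_referral"] = out["person_id"].isin(by_program["palliative_referral"])
    out["frail_ltc"] = out["person_id"].isin(by_program["nursing_home_admission"])
    out["transitional_need"] = out["person_id"].isin(
        by_program["transitional_care_enrollment"].union(
            by_program["pediatric_longterm_program"]
        )
    )

    cond = conditions.loc[
        conditions["person_id"].isin(known)
        & (conditions["first_diagnosis_date"].dt.year <= year)
    ].copy()
    cond["category"] = cond["condition_code"].map(registry).fillna(cond["category"])

    def _has(category: str) -> pd.Series:
        ids = cond.loc[cond["category"] == category, "person_id"].unique()
        return out["person_id"].isin(ids)

    out["has_cancer"] = _has("cancer")
    out["has_mental_health"] = _has("mental_health")
    out["obesity_history"] = _has("obesity")

    counting = cond.loc[cond["category"].isin(COUNTING_CATEGORIES)]
    n_chronic = counting.groupby("person_id")["condition_code"].nunique()
    out["n_chronic"] = out["person_id"].map(n_chronic).fillna(0).astype(int)

    specialist_ids = counting.loc[
        counting["condition_code"].isin(specialist_codes), "person_id"
    ].unique()
    has_specialist = out["person_id"].isin(specialist_ids)
    out["complex_chronic"] = (out["n_chronic"] >= 2) | has_specialist

    simple_ids = counting.loc[
        counting["category"] == "simple_chronic", "person_id"
    ].unique()
    out["simple_chronic"] = (
        (out["n_chronic"] == 1)
        & out["person_id"].isin(simple_ids)
        & ~out["complex_chronic"]
    )

    out["chas_blue"] = out["chas_tier"] == "blue"
    out["rental_housing"] = out["housing"] == "rental_public"
    out["lives_alone"] = out["lives_alone"].astype(bool)
    return out.reset_index(drop=True)
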