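"""Hierarchical segment classifier and Table-style summaries.

Twelve mutually exclusive segments [A]-[L] in four broad groups, tiered from
highest to lowest healthcare need.  Classification is highest-need-first:
the first rule that fires in the precedence order wins, so meeting the
criteria of a higher-need segment overrides any lower-need segment the person
would also qualify for.  Every person-year matches the catch-all "mostly
healthy" rule, so classification is total.

Default precedence (rule id = segment code):

1.  L  end of life: died in the index year or palliative referral (any age)
2.  K  frail / long-term care (adult, senior)
3.  I  transitional & long-term needs (child)
4.  J  transitional needs (adult, senior)
5.  H  cancer (adult, senior)
6.  G  mental-health condition (adult, senior)
7.  D  chronic condition (child)
8.  F  complex chronic condition (adult, senior)
9.  E  simple chronic condition (adult, senior)
10. C  at risk (senior)
11. B  at risk (child, adult)
12. A  mostly healthy (any age)

Age bands: child 0-18, adult 19-64, senior >= 65.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SEGMENTS: tuple[str, ...] = tuple("ABCDEFGHIJKL")

STAYING_HEALTHY = "staying_healthy"
LIVING_WELL = "living_well_with_illness"
GETTING_WELL = "getting_well"
MAXIMIZING = "maximizing_quality_life_years"

BROAD_GROUPS: tuple[str, ...] = (STAYING_HEALTHY, LIVING_WELL, GETTING_WELL, MAXIMIZING)

#: Canonical segment -> broad group map.  The children-with-transitional-needs
#: segment [I] is counted under "getting well" (the broad-group analysis
#: convention), not under "maximizing quality life years".
BROAD_GROUP_OF: dict[str, str] = {
    "A": STAYING_HEALTHY,
    "B": STAYING_HEALTHY,
    "C": STAYING_HEALTHY,
    "D": LIVING_WELL,
    "E": LIVING_WELL,
    "F": LIVING_WELL,
    "G": LIVING_WELL,
    "H": LIVING_WELL,
    "I": GETTING_WELL,
    "J": GETTING_WELL,
    "K": MAXIMIZING,
    "L": MAXIMIZING,
}

SEGMENT_LABELS: dict[str, str] = {
    "A": "Mostly Healthy Children, Adults & Seniors",
    "B": "At Risk Children & Adults",
    "C": "At Risk Seniors",
    "D": "Children with Chronic Condition",
    "E": "Adults and Seniors with Simple Chronic Condition",
    "F": "Adults and Seniors with Complex Chronic Condition",
    "G": "Adults and Seniors with Mental Health Condition",
    "H": "Adults and Seniors with Cancer",
    "I": "Children with Transitional & Long-Term Needs",
    "J": "Adults and Seniors with Transitional Needs",
    "K": "Frail Adults and Seniors",
    "L": "End-of-Life Children, Adults and Seniors",
}

DEFAULT_PRECEDENCE: tuple[str, ...] = ("L", "K", "I", "J", "H", "G", "D", "F", "E", "C", "B", "A")

DEFAULT_RISK_FACTORS: tuple[str, ...] = (
    "chas_blue",
    "rental_housing",
    "obesity_history",
    "lives_alone",
)


@dataclass(frozen=True)
class SegmentAssignment:
    person_id: str
    year: int
    segment: str
    broad_group: str
    matched_rule: str


@dataclass
class CriteriaConfig:
    """Tunable classification criteria; defaults reproduce the canonical hierarchy."""

    risk_factor_set: tuple[str, ...] = DEFAULT_RISK_FACTORS
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    age_band_cutoffs: tuple[int, int] = (18, 65)
    #: If True, the end-of-life rule also fires on a ``dies_next_year`` feature
    #: column (lookahead operationalization of "final year of life").
    eol_lookahead: bool = False

    def __post_init__(self) -> None:
        if sorted(self.precedence) != sorted(SEGMENTS):
            raise ValueError("precedence must contain every segment rule exactly once")
        unknown = set(self.risk_factor_set) - set(DEFAULT_RISK_FACTORS)
        if unknown:
            raise ValueError(f"unknown risk factors: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CriteriaConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("risk_factor_set", "precedence"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        if "age_band_cutoffs" in raw:
            kwargs["age_band_cutoffs"] = tuple(raw["age_band_cutoffs"])
        if "eol_lookahead" in raw:
            kwargs["eol_lookahead"] = bool(raw["eol_lookahead"])
        return cls(**kwargs)


def _rule_predicates(cfg: CriteriaConfig) -> dict[str, callable]:
    """Predicates usable on a scalar row mapping or on DataFrame columns.

    Each predicate uses only ``&``/``|`` and comparisons so the same
    expression evaluates element-wise on pandas Series and on plain booleans.
    """

    def risk_any(f):
        flags = [f[k] for k in cfg.risk_factor_set]
        out = flags[0]
        for x in flags[1:]:
            out = out | x
        return out

    def eol(f):
        fired = f["died_in_year"] | f["palliative_referral"]
        if cfg.eol_lookahead:
            try:
                fired = fired | f["dies_next_year"]
            except KeyError:
                pass
        return fired

    not_child = lambda f: f["age_band"] != "child"
    return {
        "L": eol,
        "K": lambda f: f["frail_ltc"] & not_child(f),
        "I": lambda f: f["transitional_need"] & (f["age_band"] == "child"),
        "J": lambda f: f["transitional_need"] & not_child(f),
        "H": lambda f: f["has_cancer"] & not_child(f),
        "G": lambda f: f["has_mental_health"] & not_child(f),
        "D": lambda f: (f["n_chronic"] >= 1) & (f["age_band"] == "child"),
        "F": lambda f: f["complex_chronic"] & not_child(f),
        "E": lambda f: f["simple_chronic"] & not_child(f),
        "C": lambda f: risk_any(f) & (f["age_band"] == "senior"),
        "B": lambda f: risk_any(f) & not_senior(f),
        "A": lambda f: True,  # catch-all: mostly healthy
    }


def not_senior(f):
    return f["age_band"] != "senior"


def classify_person_year(
    features: Mapping, cfg: CriteriaConfig | None = None
) -> SegmentAssignment:
    """Classify a single person-year by first-match over the precedence order."""
    cfg = cfg or CriteriaConfig()
    rules = _rule_predicates(cfg)
    for rule_id in cfg.precedence:
        if bool(rules[rule_id](features)):
            return SegmentAssignment(
                person_id=str(features.get("person_id", "")),
                year=int(features.get("year", 0)),
                segment=rule_id,
                broad_group=BROAD_GROUP_OF[rule_id],
                matched_rule=rule_id,
            )
    raise AssertionError("classification is total; the catch-all rule must fire")


def classify_population(
    features: pd.DataFrame, cfg: CriteriaConfig | None = None
) -> pd.DataFrame:
    """Vectorized classification of a feature table.

    Returns one row per input row: ``person_id, year, segment, broad_group,
    matched_rule``.  Order-invariant: a permutation of the input yields the
    same multiset of assignments.
    """
    cfg = cfg or CriteriaConfig()
    if features.empty:
        return pd.DataFrame(
            columns=["person_id", "year", "segment", "broad_group", "matched_rule"]
        )
    rules = _rule_predicates(cfg)
    conds = []
    for rule_id in cfg.precedence:
        fired = rules[rule_id](features)
        if fired is True:  # catch-all on a DataFrame path
            fired = pd.Series(True, index=features.index)
        conds.append(np.asarray(fired, dtype=bool))
    segment = np.select(conds, cfg.precedence, default=cfg.precedence[-1])
    out = features[["person_id", "year"]].copy()
    out["segment"] = segment
    out["broad_group"] = out["segment"].map(BROAD_GROUP_OF)
    out["matched_rule"] = segment
    return out.reset_index(drop=True)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table display conventions."""
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(n: float, total: float, ndigits: int = 1) -> float:
    """``100 * n / total`` rounded half-up; NaN when the denominator is 0."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * n / total, ndigits)


_ROW_ORDER = (
    ["total", STAYING_HEALTHY, "A", "B", "C", LIVING_WELL, "D", "E", "F", "G", "H"]
    + [GETTING_WELL, "I", "J", MAXIMIZING, "K", "L"]
)


def aggregate_segment_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Aggregate per-segment counts into broad-group rows, a grand total and
    percentages of the grand total (1 decimal, half-up).

    The broad-group rows equal the sums of their member-segment rows by
    construction, which is the arithmetic the printed size table displays.
    """
    counts = {s: int(counts.get(s, 0)) for s in SEGMENTS}
    total = sum(counts.values())
    rows: dict[str, int] = {"total": total}
    for g in BROAD_GROUPS:
        rows[g] = sum(n for s, n in counts.items() if BROAD_GROUP_OF[s] == g)
    rows.update(counts)
    out = pd.DataFrame(
        {
            "n": [rows[r] for r in _ROW_ORDER],
            "pct": [percentage(rows[r], total) for r in _ROW_ORDER],
        },
        index=pd.Index(_ROW_ORDER, name="row"),
    )
    return out


def tabulate_segment_sizes(
    assignments: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    by_region: bool = False,
) -> pd.DataFrame:
    """Segment/broad-group size table, overall and optionally per region.

    Columns are a MultiIndex ``(column, {'n','pct'})`` where ``column`` is
    ``'Total'`` plus, when ``by_region`` is set, each region.  Percentages are
    of the column total.  Persons with missing region count only toward the
    Total column.
    """
    seg_counts = assignments["segment"].value_counts().to_dict()
    blocks = {"Total": aggregate_segment_counts(seg_counts)}
    if by_region:
        if persons is None:
            raise ValueError("per-region tabulation requires the persons table")
        merged = assignments.merge(
            persons[["person_id", "region"]], on="person_id", how="left"
        )
        from . import records

        for region in records.REGIONS:
            sub = merged.loc[merged["region"] == region, "segment"]
            blocks[region] = aggregate_segment_counts(sub.value_counts().to_dict())
    cols = ([r for r in blocks if r != "Total"] + ["Total"]) if by_region else ["Total"]
    return pd.concat({c: blocks[c] for c in cols}, axis=1)


_DEMOG_CATEGORICALS: tuple[tuple[str, str, str], ...] = (
    # (field name in output, feature column, level)
    ("gender_male", "gender", "male"),
    ("gender_female", "gender", "female"),
    ("ethnicity_chinese", "ethnicity", "Chinese"),
    ("ethnicity_malay", "ethnicity", "Malay"),
    ("ethnicity_indian", "ethnicity", "Indian"),
    ("ethnicity_others", "ethnicity", "Others"),
    ("housing_rental_public", "housing", "rental_public"),
    ("housing_nonrental_public", "housing", "nonrental_public"),
    ("housing_private", "housing", "private"),
    ("chas_none", "chas_tier", "none"),
    ("chas_orange", "chas_tier", "orange"),
    ("chas_blue", "chas_tier", "blue"),
)


def tabulate_demographics(
    assignments: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Per-segment demographics in long format.

    One row per ``(segment, field, measure)`` with measures ``n`` (count),
    ``pct`` (within-segment percentage, 1 decimal half-up), ``mean`` and
    ``sd`` (sample SD, n-1 denominator) for age.  Empty segments yield zero
    counts and NaN percentages.
    """
    df = assignments[["person_id", "segment"]].merge(features, on="person_id")
    rows: list[tuple[str, str, str, float]] = []
    for seg in SEGMENTS:
        sub = df.loc[df["segment"] == seg]
        n = len(sub)
        rows.append((seg, "size", "n", float(n)))
        if n:
            age = sub["age"].astype(float)
            rows.append((seg, "age", "mean", round_half_up(age.mean())))
            sd = age.std(ddof=1) if n > 1 else float("nan")
            rows.append((seg, "age", "sd", round_half_up(sd) if n > 1 else float("nan")))
        else:
            rows.append((seg, "age", "mean", float("nan")))
            rows.append((seg, "age", "sd", float("nan")))
        for field_name, col, level in _DEMOG_CATEGORICALS:
            k = int((sub[col] == level).sum()) if n else 0
            rows.append((seg, field_name, "n", float(k)))
            rows.append((seg, field_name, "pct", percentage(k, n) if n else float("nan")))
        for field_name, col in (
            ("pioneer_generation", "pioneer_generation"),
            ("obesity_history", "obesity_history"),
        ):
            k = int(sub[col].astype(bool).sum()) if n else 0
            rows.append((seg, field_name, "n", float(k)))
            rows.append((seg, field_name, "pct", percentage(k, n) if n else float("nan")))
    return pd.DataFrame(rows, columns=["segment", "field", "measure", "value"])
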