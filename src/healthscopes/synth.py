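"""Synthetic linked administrative dataset with latent ground-truth segments.

Emulates the structure of a national person-year administrative extract:
a 12-segment population mixture (defaulting to the published national segment
shares), per-segment demographics (ages, gender, ethnicity, housing,
financial-assistance tier, obesity history), zero-heavy utilization counts
and lognormal charges by care setting, and segment-graded next-year outcomes
(mortality, ICU admission, utilization rates).

In strict mode (the default) the generated records deterministically satisfy
exactly the latent segment's classification rule and no higher-precedence
rule, so the hierarchy classifier recovers the latent segment for every
person — the round-trip that anchors the end-to-end tests.  Non-strict mode
injects adjacent-tier label noise for robustness testing.

The generator is a model of study conditions, not of real dollar levels:
charge medians are calibrated only so that mean per-resident charges rank the
transitional, end-of-life and frail segments far above the healthy ones, and
next-year outcome rates are graded so the broad-group orderings match the
published validation tables (highest follow-up bed days / ICU odds /
mortality hazard in the maximizing-quality-of-life tier, lowest in staying
healthy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .registry import (
    COMPLEX_CONDITIONS,
    DEFAULT_REGISTRY,
    MENTAL_HEALTH_CONDITIONS,
    SIMPLE_CONDITIONS,
)
from .segmentation import SEGMENTS
from . import records

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Published national 2016 segment sizes; the default mixture is proportional.
TABLE1_SEGMENT_COUNTS: dict[str, int] = {
    "A": 2_976_349,
    "B": 478_769,
    "C": 34_763,
    "D": 17_206,
    "E": 348_933,
    "F": 572_966,
    "G": 114_635,
    "H": 24_919,
    "I": 5_231,
    "J": 26_238,
    "K": 37_543,
    "L": 33_913,
}

TABLE1_GRAND_TOTAL = sum(TABLE1_SEGMENT_COUNTS.values())  # 4,671,465

DEFAULT_MIXTURE: dict[str, float] = {
    s: n / TABLE1_GRAND_TOTAL for s, n in TABLE1_SEGMENT_COUNTS.items()
}

REGION_PROPS = {"Central": 0.3951, "Western": 0.2812, "Eastern": 0.3237}

# Per-segment demographics: age (mean, sd, low, high truncation), male share,
# ethnicity (Chinese, Malay, Indian, Others), housing (rental, non-rental,
# private), CHAS tier (none, orange, blue), pioneer share (seniors only),
# obesity-history share, lives-alone share.  Anchored to the published
# per-segment demographics table; truncation bounds enforce each segment's
# age-band definition.
_D = {
    "A": dict(age=(29.7, 18.0, 0, 110), male=0.507, eth=(0.657, 0.076, 0.081, 0.186),
              housing=(0.0, 0.771, 0.229), chas=(0.901, 0.099, 0.0), pioneer=0.010,
              obesity=0.0, alone=0.0),
    "B": dict(age=(29.3, 18.4, 0, 64), male=0.511, eth=(0.601, 0.206, 0.073, 0.120),
              housing=(0.111, 0.864, 0.025), chas=(0.159, 0.040, 0.802), pioneer=0.0,
              obesity=0.025, alone=0.03),
    "C": dict(age=(71.9, 8.0, 65, 110), male=0.506, eth=(0.815, 0.064, 0.068, 0.052),
              housing=(0.216, 0.754, 0.030), chas=(0.363, 0.067, 0.570), pioneer=0.670,
              obesity=0.005, alone=0.15),
    "D": dict(age=(7.2, 6.2, 0, 18), male=0.558, eth=(0.597, 0.179, 0.103, 0.122),
              housing=(0.039, 0.816, 0.146), chas=(0.676, 0.114, 0.210), pioneer=0.0,
              obesity=0.015, alone=0.0),
    "E": dict(age=(49.2, 15.8, 19, 110), male=0.491, eth=(0.714, 0.110, 0.079, 0.097),
              housing=(0.032, 0.813, 0.155), chas=(0.597, 0.166, 0.237), pioneer=0.114,
              obesity=0.027, alone=0.04),
    "F": dict(age=(63.4, 12.5, 19, 110), male=0.507, eth=(0.744, 0.100, 0.084, 0.073),
              housing=(0.050, 0.831, 0.119), chas=(0.483, 0.175, 0.342), pioneer=0.385,
              obesity=0.116, alone=0.05),
    "G": dict(age=(48.5, 16.8, 19, 110), male=0.421, eth=(0.753, 0.081, 0.088, 0.079),
              housing=(0.049, 0.826, 0.125), chas=(0.534, 0.151, 0.315), pioneer=0.142,
              obesity=0.054, alone=0.06),
    "H": dict(age=(60.1, 13.5, 19, 110), male=0.366, eth=(0.826, 0.062, 0.050, 0.063),
              housing=(0.031, 0.774, 0.196), chas=(0.563, 0.148, 0.290), pioneer=0.314,
              obesity=0.058, alone=0.05),
    "I": dict(age=(7.5, 6.2, 0, 18), male=0.553, eth=(0.599, 0.172, 0.112, 0.117),
              housing=(0.045, 0.818, 0.137), chas=(0.620, 0.130, 0.250), pioneer=0.0,
              obesity=0.028, alone=0.0),
    "J": dict(age=(63.5, 17.0, 19, 110), male=0.484, eth=(0.672, 0.139, 0.103, 0.087),
              housing=(0.078, 0.836, 0.086), chas=(0.418, 0.163, 0.419), pioneer=0.460,
              obesity=0.110, alone=0.06),
    "K": dict(age=(76.5, 12.4, 19, 110), male=0.426, eth=(0.822, 0.070, 0.058, 0.050),
              housing=(0.099, 0.785, 0.115), chas=(0.407, 0.117, 0.477), pioneer=0.779,
              obesity=0.059, alone=0.10),
    "L": dict(age=(71.1, 15.5, 0, 110), male=0.543, eth=(0.737, 0.131, 0.079, 0.053),
              housing=(0.057, 0.840, 0.103), chas=(0.432, 0.136, 0.432), pioneer=0.613,
              obesity=0.087, alone=0.10),
}

#: Share of end-of-life persons who die during the index year (the published
#: validation cohort retains 15,480 of 33,913 end-of-life residents).
EOL_INDEX_DEATH_P = 0.54

# Index-year utilization: per setting, per segment (p_use, mean positive count).
_SEG_IDX = {s: i for i, s in enumerate(SEGMENTS)}

INDEX_UTILIZATION: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    #                 A     B     C     D     E     F     G     H     I     J     K     L
    "polyclinic": ((0.25, 0.45, 0.50, 0.50, 0.75, 0.90, 0.70, 0.60, 0.50, 0.80, 0.70, 0.75),
                   (1.5, 2.0, 2.0, 2.2, 2.8, 4.5, 3.0, 2.8, 2.2, 3.5, 3.0, 3.5)),
    "specialist_outpatient": ((0.05, 0.08, 0.15, 0.30, 0.35, 0.55, 0.50, 0.95, 0.85, 0.90, 0.60, 0.85),
                              (1.5, 1.5, 1.8, 2.0, 2.2, 3.0, 3.0, 7.0, 5.0, 6.0, 3.5, 5.5)),
    "emergency": ((0.04, 0.06, 0.08, 0.15, 0.10, 0.18, 0.20, 0.25, 0.40, 0.70, 0.50, 0.70),
                  (1.2, 1.2, 1.3, 1.4, 1.3, 1.4, 1.5, 1.5, 1.8, 2.0, 1.8, 2.0)),
    "inpatient_acute": ((0.015, 0.02, 0.05, 0.06, 0.06, 0.13, 0.12, 0.45, 0.50, 0.95, 0.55, 0.85),
                        (1.1, 1.1, 1.2, 1.2, 1.2, 1.4, 1.4, 2.0, 1.8, 2.2, 1.8, 2.5)),
    "day_surgery": ((0.008, 0.01, 0.03, 0.02, 0.04, 0.08, 0.05, 0.30, 0.15, 0.25, 0.10, 0.15),
                    (1.1, 1.1, 1.1, 1.1, 1.1, 1.2, 1.1, 1.5, 1.3, 1.4, 1.2, 1.3)),
    "chas_gp": ((0.05, 0.30, 0.35, 0.10, 0.30, 0.35, 0.25, 0.20, 0.10, 0.25, 0.30, 0.25),
                (1.5, 2.0, 2.2, 1.5, 2.5, 3.0, 2.5, 2.0, 1.5, 2.5, 2.5, 2.5)),
}

#: Median gross charge per encounter by setting (index year), scaled by a
#: per-segment severity multiplier; lognormal with sigma 0.7.
SETTING_CHARGE_MEDIAN = {
    "polyclinic": 45.0,
    "chas_gp": 40.0,
    "specialist_outpatient": 180.0,
    "emergency": 220.0,
    "day_surgery": 1_800.0,
    "inpatient_acute": 3_500.0,
}
SEGMENT_CHARGE_MULT = (1.0, 1.0, 1.2, 1.2, 1.3, 1.6, 1.5, 3.0, 2.5, 4.0, 2.0, 3.5)
CHARGE_SIGMA = 0.7

#: Mean bed days per acute admission (index year) by segment.
SEGMENT_LOS = (2.5, 2.5, 4.0, 3.0, 3.5, 5.0, 6.0, 6.0, 4.0, 6.5, 9.0, 8.0)
#: Probability an acute admission involves ICU (index year).
SEGMENT_ICU_ENC_P = (0.02, 0.02, 0.04, 0.05, 0.04, 0.06, 0.05, 0.12, 0.15, 0.20, 0.10, 0.25)

# Follow-up (next-year) outcome model.  Mean visit rates are the baseline
# mostly-healthy rate plus the published per-segment marginal effects, so the
# generator's true segment contrasts are the printed ME values; counts are
# exposure-scaled Poisson.
FOLLOWUP_RATES: dict[str, tuple[float, ...]] = {
    #               A     B     C     D     E     F     G     H     I     J     K     L
    "polyclinic": (0.60, 1.04, 0.91, 1.57, 1.54, 3.53, 2.32, 2.23, 1.63, 3.12, 2.57, 3.29),
    "specialist_outpatient": (0.40, 0.58, 1.09, 1.60, 1.31, 2.42, 2.79, 8.76, 5.64, 6.65, 3.98, 6.90),
    "emergency": (0.08, 0.15, 0.13, 0.28, 0.19, 0.29, 0.37, 0.40, 0.74, 1.30, 0.96, 1.50),
    "inpatient_acute": (0.05, 0.07, 0.12, 0.17, 0.12, 0.24, 0.22, 0.59, 0.83, 1.29, 0.89, 1.69),
    "bed_days": (0.25, 0.36, 1.00, 0.66, 0.58, 1.44, 1.96, 3.68, 3.12, 8.27, 8.00, 11.94),
}

#: Next-year ICU admission probability per segment: graded like the published
#: odds ratios, with the frail / end-of-life tier lifted so the broad-group
#: ordering is resolvable at synthetic sample sizes.
FOLLOWUP_ICU_P = (0.004, 0.0057, 0.023, 0.011, 0.015, 0.036, 0.021, 0.082, 0.055, 0.115, 0.09, 0.30)

#: Next-year death probability per segment (uniform death day within the year).
FOLLOWUP_DEATH_P = (0.0006, 0.001, 0.015, 0.0008, 0.004, 0.010, 0.008, 0.030, 0.005, 0.030, 0.080, 0.30)

CHILD_CHRONIC = ("asthma", "epilepsy", "diabetes", "allergic_rhinitis")

#: Precedence-tier order used for adjacent-tier label noise in non-strict mode.
_NOISE_ORDER = ("A", "B", "C", "E", "F", "D", "G", "H", "J", "I", "K", "L")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Parameters
    ----------
    n_persons
        Population size (default 50,000 — large enough that every segment,
        including the ~0.1% pediatric transitional segment, is populated).
    seed
        Master seed; population and follow-up draws derive child streams.
    year
        Index calendar year.
    segment_mixture
        Probability per segment; defaults to the published national shares.
    strict
        Generate features that satisfy exactly the latent segment's rule.
    label_noise
        Non-strict only: probability a person's features are drawn from an
        adjacent-need tier instead of the latent segment.
    death_p / icu_p
        Optional per-segment overrides of the next-year death / ICU
        probabilities (missing segments keep the defaults).
    rate_multiplier
        Optional per-segment multiplier applied to every next-year
        utilization rate (visits and bed days).
    """

    n_persons: int = 50_000
    seed: int = 0
    year: int = 2016
    segment_mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    strict: bool = True
    label_noise: float = 0.0
    death_p: Mapping[str, float] | None = None
    icu_p: Mapping[str, float] | None = None
    rate_multiplier: Mapping[str, float] | None = None

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        unknown = set(self.segment_mixture) - set(SEGMENTS)
        if unknown:
            raise ValueError(f"unknown segment code(s) in mixture: {sorted(unknown)}")
        probs = np.array([self.segment_mixture.get(s, 0.0) for s in SEGMENTS], float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("segment_mixture must be nonnegative and sum to 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        for name, override in (("death_p", self.death_p), ("icu_p", self.icu_p)):
            if override is not None:
                bad = {s: p for s, p in override.items() if s not in SEGMENTS or not 0 <= p <= 1}
                if bad:
                    raise ValueError(f"{name}: invalid override entries {bad}")
        if self.rate_multiplier is not None:
            bad = {s: m for s, m in self.rate_multiplier.items() if s not in SEGMENTS or m < 0}
            if bad:
                raise ValueError(f"rate_multiplier: invalid override entries {bad}")

    def _followup_vector(self, defaults: tuple[float, ...], override) -> np.ndarray:
        out = np.asarray(defaults, float).copy()
        for s, v in (override or {}).items():
            out[_SEG_IDX[s]] = v
        return out


@dataclass
class SyntheticPopulation:
    """Generated linked dataset plus latent ground truth."""

    year: int
    persons: pd.DataFrame
    conditions: pd.DataFrame
    programs: pd.DataFrame
    encounters: pd.DataFrame
    latent: pd.DataFrame  # person_id, latent_segment
    followup: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "conditions": self.conditions,
            "programs": self.programs,
            "encounters": self.encounters,
        }


def _truncnorm_ages(rng, mean, sd, low, high, size) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(x), low, high).astype(int)


def _choice(rng, levels, probs, size):
    p = np.asarray(probs, float)
    return rng.choice(np.asarray(levels, object), size=size, p=p / p.sum())


def _distinct_pairs(rng, codes, size):
    """Two distinct codes per row from ``codes``."""
    k = len(codes)
    i = rng.integers(0, k, size)
    j = (i + 1 + rng.integers(0, k - 1, size)) % k
    arr = np.asarray(codes, object)
    return arr[i], arr[j]


def _dates_in_year(rng, year, size, max_day=None):
    day = rng.integers(1, 366, size)
    if max_day is not None:
        day = np.minimum(day, max_day)
    return pd.Timestamp(year, 1, 1) + pd.to_timedelta(day - 1, unit="D")


def generate_population(cfg: SyntheticConfig) -> SyntheticPopulation:
    """Draw a full linked dataset under the configured study conditions.

    Reproducible: the same config and seed yield byte-identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    n, year = cfg.n_persons, cfg.year

    mixture = np.array([cfg.segment_mixture.get(s, 0.0) for s in SEGMENTS], float)
    latent_idx = rng.choice(len(SEGMENTS), size=n, p=mixture / mixture.sum())

    # Features are generated from an "effective" segment, which differs from
    # the latent label for noisy persons in non-strict mode.
    eff_idx = latent_idx.copy()
    if not cfg.strict and cfg.label_noise > 0:
        noisy = rng.random(n) < cfg.label_noise
        pos = np.array([_NOISE_ORDER.index(s) for s in SEGMENTS])[latent_idx]
        shift = rng.choice([-1, 1], size=n)
        new_pos = np.clip(pos + shift, 0, len(SEGMENTS) - 1)
        back = np.array([_SEG_IDX[s] for s in _NOISE_ORDER])
        eff_idx[noisy] = back[new_pos[noisy]]

    person_id = np.array([f"P{i:07d}" for i in range(n)], object)
    age = np.zeros(n, int)
    gender = np.empty(n, object)
    ethnicity = np.empty(n, object)
    housing = np.empty(n, object)
    chas = np.empty(n, object)
    pioneer = np.zeros(n, bool)
    alone = np.zeros(n, bool)
    obesity = np.zeros(n, bool)

    for si, seg in enumerate(SEGMENTS):
        m = eff_idx == si
        k = int(m.sum())
        if not k:
            continue
        d = _D[seg]
        age[m] = _truncnorm_ages(rng, *d["age"], size=k)
        gender[m] = _choice(rng, records.GENDERS, (d["male"], 1 - d["male"]), k)
        ethnicity[m] = _choice(rng, records.ETHNICITIES, d["eth"], k)
        housing[m] = _choice(rng, records.HOUSING_TYPES, d["housing"], k)
        chas[m] = _choice(rng, records.CHAS_TIERS, d["chas"], k)
        obesity[m] = rng.random(k) < d["obesity"]
        alone[m] = rng.random(k) < d["alone"]
        pioneer[m] = (rng.random(k) < d["pioneer"]) & (age[m] >= 65)

    # At-risk segments need at least one risk factor: default to the dominant
    # one (CHAS Blue) when none was drawn.  The healthy segment's parameters
    # already put zero mass on every risk factor.
    at_risk = np.isin(eff_idx, [_SEG_IDX["B"], _SEG_IDX["C"]])
    no_risk = at_risk & ~(obesity | alone | (housing == "rental_public") | (chas == "blue"))
    chas[no_risk] = "blue"

    region = _choice(rng, records.REGIONS, tuple(REGION_PROPS.values()), n)

    # Index-year deaths: only end-of-life persons (any other in-year death
    # would place the person in the end-of-life segment by definition).
    eol = eff_idx == _SEG_IDX["L"]
    dies = eol & (rng.random(n) < EOL_INDEX_DEATH_P)
    death_day = np.where(dies, rng.integers(1, 366, n), 0)
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[dies] = pd.Timestamp(year, 1, 1) + pd.to_timedelta(death_day[dies] - 1, unit="D")
    # Encounters and program events are dated before death.
    max_day = np.where(dies, death_day, 365)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "birth_year": year - age,
            "gender": gender,
            "ethnicity": ethnicity,
            "housing": housing,
            "chas_tier": chas,
            "pioneer_generation": pioneer,
            "lives_alone": alone,
            "region": region,
            "death_date": death_date,
        }
    )

    conditions = _generate_conditions(rng, cfg, person_id, eff_idx, age, obesity)
    programs = _generate_programs(rng, cfg, person_id, eff_idx, dies, max_day)
    encounters = _generate_encounters(rng, cfg, person_id, eff_idx, max_day)
    latent = pd.DataFrame(
        {"person_id": person_id, "latent_segment": np.array(SEGMENTS, object)[latent_idx]}
    )
    return SyntheticPopulation(
        year=year,
        persons=persons,
        conditions=conditions,
        programs=programs,
        encounters=encounters,
        latent=latent,
    )


def _empty_table(name: str) -> pd.DataFrame:
    """Schema-conformant empty table with parsed date columns."""
    df = pd.DataFrame(columns=records.TABLE_SCHEMAS[name])
    for col in ("first_diagnosis_date", "event_date", "encounter_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def _cond_rows(rng, cfg, pid, age, codes, registry=DEFAULT_REGISTRY):
    """Condition rows with diagnosis dates on or before the index year end."""
    k = len(pid)
    years_ago = np.minimum(rng.integers(0, 16, k), np.maximum(age, 0))
    diag_year = cfg.year - years_ago
    day = rng.integers(1, 366, k)
    # day 1..365 from Jan 1 stays inside diag_year for any calendar year
    dates = pd.to_datetime(
        {"year": diag_year, "month": np.ones(k, int), "day": np.ones(k, int)}
    ) + pd.to_timedelta(day - 1, unit="D")
    return pd.DataFrame(
        {
            "person_id": pid,
            "condition_code": codes,
            "first_diagnosis_date": dates.values,
            "category": [registry[c] for c in codes],
        }
    )


def _generate_conditions(rng, cfg, person_id, eff_idx, age, obesity):
    chunks = []

    def add(mask, codes):
        if mask.sum():
            chunks.append(_cond_rows(rng, cfg, person_id[mask], age[mask], codes))

    def bern(mask, p):
        out = np.zeros_like(mask)
        out[mask] = rng.random(int(mask.sum())) < p
        return out

    seg = lambda s: eff_idx == _SEG_IDX[s]

    # children with chronic conditions
    for s in ("D", "I"):
        m = seg(s) if s == "D" else seg(s) & bern(seg(s), 0.7)
        m = m.astype(bool)
        if m.sum():
            add(m, rng.choice(np.asarray(CHILD_CHRONIC, object), int(m.sum())))
    # pediatric cancer / mental-health (routes via the chronic-child rule)
    for s, p_ca, p_mh in (("D", 0.04, 0.05), ("I", 0.05, 0.04)):
        ca = bern(seg(s), p_ca)
        if ca.sum():
            add(ca, np.repeat("cancer", int(ca.sum())))
        mh = bern(seg(s), p_mh)
        if mh.sum():
            add(mh, rng.choice(np.asarray(MENTAL_HEALTH_CONDITIONS, object), int(mh.sum())))

    # simple chronic: exactly one primary-care-manageable condition
    e = seg("E")
    if e.sum():
        add(e, rng.choice(np.asarray(SIMPLE_CONDITIONS, object), int(e.sum())))

    # complex chronic: one specialist-care condition or two distinct simples
    f = seg("F")
    if f.sum():
        via_complex = bern(f, 0.55)
        via_two = f & ~via_complex
        if via_complex.sum():
            add(via_complex, rng.choice(np.asarray(COMPLEX_CONDITIONS, object), int(via_complex.sum())))
            extra = bern(via_complex, 0.6)
            if extra.sum():
                add(extra, rng.choice(np.asarray(SIMPLE_CONDITIONS, object), int(extra.sum())))
        if via_two.sum():
            c1, c2 = _distinct_pairs(rng, SIMPLE_CONDITIONS, int(via_two.sum()))
            add(via_two, c1)
            add(via_two, c2)

    # mental health (no cancer: cancer outranks the mental-health rule)
    g = seg("G")
    if g.sum():
        add(g, rng.choice(np.asarray(MENTAL_HEALTH_CONDITIONS, object), int(g.sum())))
        extra = bern(g, 0.4)
        if extra.sum():
            add(extra, rng.choice(np.asarray(SIMPLE_CONDITIONS, object), int(extra.sum())))

    # cancer (may carry mental-health and chronic comorbidity)
    h = seg("H")
    if h.sum():
        add(h, np.repeat("cancer", int(h.sum())))
        for pool, p in ((MENTAL_HEALTH_CONDITIONS, 0.06), (SIMPLE_CONDITIONS, 0.4)):
            extra = bern(h, p)
            if extra.sum():
                add(extra, rng.choice(np.asarray(pool, object), int(extra.sum())))

    # higher tiers: comorbidity allowed freely (overridden by their own rule)
    for s, plan in (
        ("J", ((SIMPLE_CONDITIONS, 0.5), (COMPLEX_CONDITIONS, 0.25), (("cancer",), 0.08), (MENTAL_HEALTH_CONDITIONS, 0.06))),
        ("K", ((SIMPLE_CONDITIONS, 0.5), (COMPLEX_CONDITIONS, 0.35), (("cancer",), 0.05), (MENTAL_HEALTH_CONDITIONS, 0.10))),
        ("L", ((SIMPLE_CONDITIONS, 0.4), (COMPLEX_CONDITIONS, 0.4), (("cancer",), 0.45), (MENTAL_HEALTH_CONDITIONS, 0.08))),
    ):
        for pool, p in plan:
            m = bern(seg(s), p)
            if m.sum():
                add(m, rng.choice(np.asarray(pool, object), int(m.sum())))

    # obesity history as a registry diagnosis
    if obesity.sum():
        add(obesity, np.repeat("obesity", int(obesity.sum())))

    if not chunks:
        return _empty_table("conditions")
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["person_id", "condition_code"], kind="stable").reset_index(drop=True)


def _generate_programs(rng, cfg, person_id, eff_idx, dies, max_day):
    chunks = []
    year = cfg.year

    def add(mask, program):
        k = int(mask.sum())
        if k:
            chunks.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[mask],
                        "program": program,
                        "event_date": _dates_in_year(rng, year, k, max_day[mask]),
                    }
                )
            )

    seg = lambda s: eff_idx == _SEG_IDX[s]
    add(seg("I"), "pediatric_longterm_program")
    add(seg("J"), "transitional_care_enrollment")
    add(seg("K"), "nursing_home_admission")
    # End of life: everyone not dying in-year holds a palliative referral, and
    # some decedents carry one too.
    l = seg("L")
    palliative = l & (~dies | (rng.random(len(dies)) < 0.4))
    add(palliative, "palliative_referral")

    if not chunks:
        return _empty_table("programs")
    return pd.concat(chunks, ignore_index=True).sort_values(
        ["person_id", "program"], kind="stable"
    ).reset_index(drop=True)


def _generate_encounters(rng, cfg, person_id, eff_idx, max_day):
    chunks = []
    year = cfg.year
    mult = np.asarray(SEGMENT_CHARGE_MULT)
    for setting, (p_use, mean_count) in INDEX_UTILIZATION.items():
        p = np.asarray(p_use)[eff_idx]
        users = rng.random(len(eff_idx)) < p
        k = int(users.sum())
        if not k:
            continue
        counts = 1 + rng.poisson(np.asarray(mean_count)[eff_idx][users] - 1.0)
        pid = np.repeat(person_id[users], counts)
        seg_rows = np.repeat(eff_idx[users], counts)
        cap = np.repeat(max_day[users], counts)
        total = len(pid)
        median = SETTING_CHARGE_MEDIAN[setting] * mult[seg_rows]
        charges = rng.lognormal(np.log(median), CHARGE_SIGMA, total).round(2)
        if setting in records.INPATIENT_SETTINGS:
            los = np.asarray(SEGMENT_LOS)[seg_rows]
            bed_days = 1 + rng.poisson(los - 1.0)
            icu = rng.random(total) < np.asarray(SEGMENT_ICU_ENC_P)[seg_rows]
        else:
            bed_days = np.zeros(total, int)
            icu = np.zeros(total, bool)
        chunks.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "setting": setting,
                    "encounter_date": _dates_in_year(rng, year, total, cap),
                    "charges": charges,
                    "bed_days": bed_days,
                    "icu_flag": icu,
                    "specialty": "",
                }
            )
        )
    if not chunks:
        return _empty_table("encounters")
    return pd.concat(chunks, ignore_index=True).sort_values(
        ["person_id", "setting", "encounter_date"], kind="stable"
    ).reset_index(drop=True)


def generate_followup(pop: SyntheticPopulation, cfg: SyntheticConfig) -> pd.DataFrame:
    """Next-year outcomes for persons alive at the end of the index year.

    Deaths are drawn per segment with a uniform death day; visit counts are
    Poisson with mean ``segment rate x exposure`` where exposure is the
    fraction of the follow-up year alive; bed days accumulate per admission;
    the ICU flag is a per-segment Bernoulli draw.  The returned frame has one
    row per surviving person and is attached to ``pop.followup``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    alive = pop.persons["death_date"].isna().to_numpy()
    pid = pop.persons.loc[alive, "person_id"].to_numpy()
    seg = pop.latent.loc[alive, "latent_segment"].map(_SEG_IDX).to_numpy()
    k = len(pid)

    mult = cfg._followup_vector(tuple([1.0] * len(SEGMENTS)), cfg.rate_multiplier)
    died = rng.random(k) < cfg._followup_vector(FOLLOWUP_DEATH_P, cfg.death_p)[seg]
    death_day = np.where(died, rng.integers(1, 366, k), 0)
    exposure = np.where(died, death_day / 365.0, 1.0)

    out = pd.DataFrame({"person_id": pid})
    for setting in ("polyclinic", "specialist_outpatient", "emergency", "inpatient_acute"):
        rate = np.asarray(FOLLOWUP_RATES[setting])[seg] * mult[seg]
        out[setting] = rng.poisson(rate * exposure)
    adm = out["inpatient_acute"].to_numpy()
    adm_rate = np.asarray(FOLLOWUP_RATES["inpatient_acute"])[seg]
    los = np.asarray(FOLLOWUP_RATES["bed_days"])[seg] / adm_rate  # mean days/admission
    out["bed_days"] = adm + rng.poisson(adm * np.maximum(los - 1.0, 0.0))
    out["icu"] = rng.random(k) < cfg._followup_vector(FOLLOWUP_ICU_P, cfg.icu_p)[seg]
    out["died"] = died
    out["death_day"] = np.where(died, death_day, np.nan)
    pop.followup = out
    return out


def write_population(pop: SyntheticPopulation, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input CSVs plus latent truth and follow-up tables."""
    out_dir = Path(out_dir)
    written = records.write_tables(pop.tables(), out_dir)
    latent_path = out_dir / "latent_segments.csv"
    pop.latent.to_csv(latent_path, index=False)
    written["latent_segments"] = latent_path
    if pop.followup is not None:
        fu_path = out_dir / "followup.csv"
        pop.followup.to_csv(fu_path, index=False)
        written["followup"] = fu_path
    return written
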