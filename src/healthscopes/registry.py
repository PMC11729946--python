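"""Chronic-condition registry: maps condition codes to framework categories.

The registry emulates a national chronic-disease programme list (twenty-odd
conditions managed across hospitals, polyclinics and GP clinics).  Each code
belongs to exactly one category:

``simple_chronic``
    conditions manageable primarily in primary care,
``complex_chronic``
    conditions that require some specialist management,
``mental_health`` / ``cancer``
    tracked separately because they drive their own segments,
``obesity``
    a historical risk-factor diagnosis (BMI >= 27.5 kg/m2, the Asian-population
    cutoff), never counted as a chronic condition by the classifier.

The list is configurable: any mapping ``code -> category`` with categories
drawn from :data:`CATEGORIES` is accepted wherever a registry is expected.
"""

from __future__ import annotations

CATEGORIES = (
    "simple_chronic",
    "complex_chronic",
    "mental_health",
    "cancer",
    "obesity",
)

SIMPLE_CONDITIONS = (
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "asthma",
    "osteoarthritis",
    "allergic_rhinitis",
)

COMPLEX_CONDITIONS = (
    "ischaemic_heart_disease",
    "heart_failure",
    "stroke",
    "copd",
    "chronic_kidney_disease",
    "dementia",
    "parkinsons_disease",
    "epilepsy",
    "rheumatoid_arthritis",
)

MENTAL_HEALTH_CONDITIONS = (
    "major_depression",
    "schizophrenia",
    "bipolar_disorder",
    "anxiety",
)

DEFAULT_REGISTRY: dict[str, str] = {
    **{c: "simple_chronic" for c in SIMPLE_CONDITIONS},
    **{c: "complex_chronic" for c in COMPLEX_CONDITIONS},
    **{c: "mental_health" for c in MENTAL_HEALTH_CONDITIONS},
    "cancer": "cancer",
    "obesity": "obesity",
}

#: Categories whose conditions count toward ``n_chronic``.  Obesity is a risk
#: factor, not a chronic condition, so it is excluded; mental-health and
#: cancer codes do count, which is what routes e.g. a child with cancer and no
#: transitional needs into the pediatric chronic segment.
COUNTING_CATEGORIES = frozenset(
    {"simple_chronic", "complex_chronic", "mental_health", "cancer"}
)


def specialist_care_codes(registry: dict[str, str] | None = None) -> frozenset[str]:
    """Codes in the "requires specialist care" set (default: complex category).

    A single condition from this set is enough to mark a person as having
    complex chronic disease even when their total condition count is one.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    return frozenset(c for c, cat in registry.items() if cat == "complex_chronic")


def validate_registry(registry: dict[str, str]) -> None:
    bad = {c: cat for c, cat in registry.items() if cat not in CATEGORIES}
    if bad:
        raise ValueError(f"unknown condition categories: {bad}")
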