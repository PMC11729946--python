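"""Cross-sectional index-year utilization: charges and visit frequencies.

Charges are gross unsubsidized bill amounts summed per segment and per care
setting; every resident of a segment counts in the per-resident denominator
whether or not they had any encounter, so the mean is total segment charges
over segment size.  Charges attribute to the person's index-year segment
regardless of encounter month.
"""

from __future__ import annotations

import logging

import pandas as pd

from .records import INPATIENT_SETTINGS, SETTINGS
from .segmentation import SEGMENTS

logger = logging.getLogger(__name__)


def _assigned_encounters(assignments: pd.DataFrame, encounters: pd.DataFrame, year: int):
    enc = encounters.loc[encounters["encounter_date"].dt.year == year]
    merged = enc.merge(assignments[["person_id", "segment"]], on="person_id", how="left")
    unassigned = merged["segment"].isna()
    if unassigned.any():
        logger.warning("%d encounter(s) for unassigned persons excluded", int(unassigned.sum()))
    return merged.loc[~unassigned]


def summarize_charges(
    assignments: pd.DataFrame, encounters: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Per-segment charge summary.

    Returns one row per segment: per-setting charge totals, the segment total
    (their sum), segment size and mean charges per resident.  Segments with
    no encounters report zero totals and zero mean.
    """
    merged = _assigned_encounters(assignments, encounters, year)
    by_setting = (
        merged.pivot_table(
            index="segment", columns="setting", values="charges", aggfunc="sum", fill_value=0.0
        )
        .reindex(index=SEGMENTS, columns=SETTINGS, fill_value=0.0)
        .rename(columns=lambda s: f"charges_{s}")
    )
    n_residents = (
        assignments["segment"].value_counts().reindex(SEGMENTS, fill_value=0).rename("n_residents")
    )
    out = by_setting.copy()
    out["total_segment_charges"] = by_setting.sum(axis=1)
    out["n_residents"] = n_residents
    out["mean_per_resident_charges"] = (
        out["total_segment_charges"].where(out["n_residents"] > 0, 0.0)
        / out["n_residents"].replace(0, 1)
    )
    out.index.name = "segment"
    return out.reset_index()


def summarize_counts(
    assignments: pd.DataFrame, encounters: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Per-segment visit counts per setting, plus bed days for inpatient care."""
    merged = _assigned_encounters(assignments, encounters, year)
    visits = (
        merged.pivot_table(
            index="segment", columns="setting", values="person_id", aggfunc="count", fill_value=0
        )
        .reindex(index=SEGMENTS, columns=SETTINGS, fill_value=0)
        .rename(columns=lambda s: f"visits_{s}")
    )
    out = visits.copy()
    for setting in INPATIENT_SETTINGS:
        bd = (
            merged.loc[merged["setting"] == setting]
            .groupby("segment")["bed_days"]
            .sum()
            .reindex(SEGMENTS, fill_value=0)
        )
        out[f"bed_days_{setting}"] = bd
    out["n_residents"] = (
        assignments["segment"].value_counts().reindex(SEGMENTS, fill_value=0)
    )
    out.index.name = "segment"
    return out.reset_index()
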