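"""Reproducible end-to-end pipeline: synth -> segment -> charges -> validate.

A single YAML config drives all stages; every source of randomness derives
from one master seed, so rerunning an identical config reproduces identical
output digests for every deterministic stage (bootstrap seeds included).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .charges import summarize_charges, summarize_counts
from .records import apply_exclusions, assemble_person_year, read_tables
from .segmentation import (
    CriteriaConfig,
    SEGMENTS,
    classify_population,
    tabulate_demographics,
    tabulate_segment_sizes,
)
from .synth import SyntheticConfig, generate_followup, generate_population, write_population
from .validation import (
    FAMILIES,
    OUTCOMES,
    build_cohort,
    default_reference,
    fit_cox_hr,
    fit_logistic_or,
    marginal_effects,
    select_family,
)

logger = logging.getLogger(__name__)

STAGES = ("synth", "segment", "charges", "validate")


class ConfigError(ValueError):
    """The pipeline config failed schema validation (no stage has run)."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    problems: list[str] = []
    out = dict(cfg)
    if not isinstance(out.get("seed", 0), int):
        problems.append("seed must be an integer")
    out.setdefault("seed", 0)
    out.setdefault("year", 2016)
    out.setdefault("n_persons", 50_000)
    out.setdefault("strict", True)
    if not (isinstance(out["n_persons"], int) and out["n_persons"] > 0):
        problems.append("n_persons must be a positive integer")
    mixture = out.get("segment_mixture")
    if mixture is not None:
        unknown = set(mixture) - set(SEGMENTS)
        if unknown:
            problems.append(f"unknown segment code(s) in mixture: {sorted(unknown)}")
        else:
            total = sum(mixture.values())
            if any(v < 0 for v in mixture.values()) or abs(total - 1.0) > 1e-6:
                problems.append("segment_mixture must be nonnegative and sum to 1")
    val = dict(out.get("validate") or {})
    val.setdefault("grouping", "broad_group")
    val.setdefault("outcomes", ["bed_days"])
    val.setdefault("families", list(FAMILIES))
    val.setdefault("bootstrap", 200)
    if val["grouping"] not in ("broad_group", "segment"):
        problems.append("validate.grouping must be 'broad_group' or 'segment'")
    bad = [o for o in val["outcomes"] if o not in OUTCOMES]
    if bad:
        problems.append(f"unknown validation outcome(s): {bad}")
    bad = [f for f in val["families"] if f not in FAMILIES]
    if bad:
        problems.append(f"unknown families: {bad}")
    out["validate"] = val
    if problems:
        raise ConfigError("; ".join(problems))
    return out


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> RunManifest:
    """Execute all stages in dependency order and write a run manifest.

    Raises :class:`ConfigError` before any stage runs if the config is
    invalid.  Stage failures halt the run with the stage named.
    """
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text()) or {}
    else:
        raw = dict(config)
    cfg = _validate_config(raw)
    out_dir = Path(out_dir or cfg.get("out_dir", "healthscopes_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    canon = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest(),
        seed=cfg["seed"],
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def record(stage: str, paths: Mapping[str, Path], counts: Mapping[str, int] | None = None):
        manifest.stages.append(
            {
                "stage": stage,
                "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in paths.values()},
                "counts": dict(counts or {}),
            }
        )

    year = cfg["year"]
    # --- synth ---
    scfg = SyntheticConfig(
        n_persons=cfg["n_persons"],
        seed=cfg["seed"],
        year=year,
        strict=cfg["strict"],
        label_noise=float(cfg.get("label_noise", 0.0)),
        **({"segment_mixture": cfg["segment_mixture"]} if cfg.get("segment_mixture") else {}),
    )
    pop = generate_population(scfg)
    generate_followup(pop, scfg)
    data_dir = out_dir / "data"
    written = write_population(pop, data_dir)
    record("synth", written, {"n_persons": len(pop.persons)})

    # --- segment ---
    tables = read_tables({t: data_dir / f"{t}.csv" for t in ("persons", "conditions", "programs", "encounters")})
    base = apply_exclusions(tables["persons"], year)
    features = assemble_person_year(base, tables["conditions"], tables["programs"], tables["encounters"])
    criteria = CriteriaConfig.from_yaml(cfg["criteria"]) if cfg.get("criteria") else CriteriaConfig()
    assignments = classify_population(features, criteria)
    seg_paths = {}
    for name, df in (
        ("assignments", assignments),
        ("segment_sizes", tabulate_segment_sizes(assignments, base.persons, by_region=True)),
        ("demographics", tabulate_demographics(assignments, features)),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=isinstance(df.index, pd.MultiIndex) or name == "segment_sizes")
        seg_paths[name] = p
    record("segment", seg_paths, {"n_classified": len(assignments), **base.excluded_counts})

    # --- charges ---
    charge_paths = {}
    for name, df in (
        ("charges", summarize_charges(assignments, tables["encounters"], year)),
        ("utilization_counts", summarize_counts(assignments, tables["encounters"], year)),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        charge_paths[name] = p
    record("charges", charge_paths)

    # --- validate ---
    val = cfg["validate"]
    followup = pd.read_csv(data_dir / "followup.csv")
    died_ids = features.loc[features["died_in_year"], "person_id"]
    cohort = build_cohort(assignments, followup, died_in_index_year=died_ids)
    grouping = val["grouping"]
    me_frames = []
    for outcome in val["outcomes"]:
        fit = select_family(cohort, outcome, grouping, candidates=val["families"])
        me = marginal_effects(fit, cohort, n_boot=val["bootstrap"], seed=cfg["seed"] + 1)
        me.insert(0, "outcome", outcome)
        me.insert(1, "family", fit.family)
        me.insert(2, "aic_per_obs", fit.aic_per_obs)
        me_frames.append(me)
    val_paths = {}
    outputs = {
        "validation_me": pd.concat(me_frames, ignore_index=True),
        "validation_or": fit_logistic_or(cohort, grouping),
        "validation_hr": fit_cox_hr(cohort, grouping),
    }
    for name, df in outputs.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        val_paths[name] = p
    record("validate", val_paths, {"cohort_n": len(cohort)})

    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
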