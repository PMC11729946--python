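"""Two-part, logistic and Cox model behaviour against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

import healthscopes as hs
from healthscopes.segmentation import LIVING_WELL, MAXIMIZING, STAYING_HEALTHY
from healthscopes.validation import (
    ValidationCohort,
    _fast_bootstrap_draws,
    _point_me,
    fit_two_part,
)

REF = STAYING_HEALTHY
ALT = LIVING_WELL


def two_group_cohort(y_ref, y_alt, exposure_ref=None, exposure_alt=None):
    n1, n2 = len(y_ref), len(y_alt)
    e1 = np.ones(n1) if exposure_ref is None else np.asarray(exposure_ref, float)
    e2 = np.ones(n2) if exposure_alt is None else np.asarray(exposure_alt, float)
    df = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n1 + n2)],
            "segment": ["A"] * n1 + ["E"] * n2,
            "broad_group": [REF] * n1 + [ALT] * n2,
            "polyclinic": np.concatenate([y_ref, y_alt]),
            "icu": False,
            "died": False,
            "death_day": np.nan,
            "exposure": np.concatenate([e1, e2]),
            "duration": 365.0,
            "event": False,
        }
    )
    return ValidationCohort(year=2017, df=df)


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------


def test_cohort_excludes_index_year_deaths_and_computes_exposure():
    n = 100
    asg = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "segment": "A",
            "broad_group": REF,
        }
    )
    fu = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(10, n)],
            "polyclinic": 0,
            "specialist_outpatient": 0,
            "emergency": 0,
            "inpatient_acute": 0,
            "bed_days": 0,
            "icu": False,
            "died": [True] + [False] * 89,
            "death_day": [73.0] + [np.nan] * 89,
        }
    )
    died_index = [f"P{i}" for i in range(10)]
    cohort = hs.build_cohort(asg, fu, died_in_index_year=died_index)
    assert len(cohort) == 90
    row = cohort.df.set_index("person_id").loc["P10"]
    assert row["exposure"] == pytest.approx(0.2)
    assert row["duration"] == 73.0 and row["event"]
    alive = cohort.df.loc[~cohort.df["event"]]
    assert (alive["exposure"] == 1.0).all() and (alive["duration"] == 365.0).all()


def test_followup_without_assignment_is_dropped_with_warning():
    asg = pd.DataFrame({"person_id": ["P1"], "segment": "A", "broad_group": REF})
    fu = pd.DataFrame(
        {
            "person_id": ["P1", "GHOST"],
            "polyclinic": 1, "specialist_outpatient": 0, "emergency": 0,
            "inpatient_acute": 0, "bed_days": 0, "icu": False,
            "died": False, "death_day": np.nan,
        }
    )
    cohort = hs.build_cohort(asg, fu)
    assert len(cohort) == 1
    assert cohort.warnings["followup_without_assignment"] == 1


# ---------------------------------------------------------------------------
# two-part model
# ---------------------------------------------------------------------------


def test_reference_marginal_effect_is_exactly_zero(small_cohort):
    fit = hs.fit_two_part(small_cohort, "polyclinic", "broad_group", family="poisson")
    me = hs.marginal_effects(fit, small_cohort, n_boot=50, seed=1)
    ref_row = me.set_index("group").loc[REF]
    assert ref_row["me"] == 0.0 and ref_row["ci_low"] == 0.0 and ref_row["ci_high"] == 0.0


def test_all_positive_outcomes_collapse_to_single_glm():
    rng = np.random.default_rng(8)
    y1 = 1 + rng.poisson(1.0, 800)
    y2 = 1 + rng.poisson(3.0, 800)
    cohort = two_group_cohort(y1, y2)
    fit = hs.fit_two_part(cohort, "polyclinic", "broad_group", family="poisson")
    assert fit.part1_params is None  # probability-1 shortcut
    import statsmodels.api as sm

    X = np.column_stack([np.ones(1600), np.r_[np.zeros(800), np.ones(800)]])
    glm = sm.GLM(np.r_[y1, y2], X, family=sm.families.Poisson()).fit()
    pred_two_part = fit.predict_mean(ALT, np.ones(1))[0]
    pred_glm = float(np.exp(glm.params[0] + glm.params[1]))
    assert pred_two_part == pytest.approx(pred_glm, rel=1e-8)


def test_poisson_offset_scales_expected_counts():
    rng = np.random.default_rng(3)
    e = rng.uniform(0.2, 1.0, 1000)
    y = rng.poisson(2.0 * e)
    cohort = two_group_cohort(y[:500], y[500:], e[:500], e[500:])
    fit = hs.fit_two_part(
        cohort, "polyclinic", "broad_group", family="poisson", offset_parts="part2"
    )
    base = fit.predict_mean(ALT, np.array([0.5]))
    doubled = fit.predict_mean(ALT, np.array([1.0]))
    assert doubled[0] == pytest.approx(2 * base[0], rel=1e-10)


def test_marginal_effect_matches_direct_formula_from_coefficients():
    rng = np.random.default_rng(12)
    y1 = rng.poisson(0.8, 600)
    y2 = rng.poisson(2.5, 600)
    e = np.r_[np.ones(600), rng.uniform(0.3, 1.0, 600)]
    cohort = two_group_cohort(y1, y2, e[:600], e[600:])
    fit = hs.fit_two_part(cohort, "polyclinic", "broad_group", family="poisson")
    me = hs.marginal_effects(fit, cohort, n_boot=10, seed=0).set_index("group")

    # independent recomputation from the fitted coefficients
    exposure = cohort.df["exposure"].to_numpy()
    log_e = np.log(exposure)
    b = fit.part1_params
    c = fit.part2_params
    key = f"[{ALT}]"

    def ey(group):
        b_g = b.get(key, 0.0) if group == ALT else 0.0
        c_g = c.get(key, 0.0) if group == ALT else 0.0
        return expit(b["intercept"] + b_g + log_e) * np.exp(c["intercept"] + c_g + log_e)

    expected = np.mean(ey(ALT) - ey(REF))
    assert me.loc[ALT, "me"] == pytest.approx(expected, rel=1e-10)


def test_fast_bootstrap_equals_full_refits_on_shared_resamples():
    rng = np.random.default_rng(21)
    y1 = rng.poisson(1.0, 150)
    y2 = rng.poisson(3.0, 150)
    cohort = two_group_cohort(y1, y2)
    fit = hs.fit_two_part(cohort, "polyclinic", "broad_group", family="poisson")
    n = len(cohort.df)
    y = cohort.df["polyclinic"].to_numpy(float)
    gcodes = (cohort.df["broad_group"] == ALT).to_numpy().astype(int)

    B = 10
    fast = _fast_bootstrap_draws(y, gcodes, 2, 0, B, np.random.default_rng(99))
    slow = np.empty((B, 2))
    rng2 = np.random.default_rng(99)
    for b in range(B):
        idx = rng2.integers(0, n, n)
        boot = ValidationCohort(2017, cohort.df.iloc[idx].reset_index(drop=True))
        bfit = fit_two_part(boot, "polyclinic", "broad_group", REF, "poisson")
        bme = _point_me(bfit, boot.df["exposure"].to_numpy(float))
        slow[b] = [bme[REF], bme[ALT]]
    np.testing.assert_allclose(fast[:, 1], slow[:, 1], rtol=1e-7, atol=1e-9)


def test_two_group_poisson_marginal_effect_recovery():
    rng = np.random.default_rng(17)
    y1 = rng.poisson(1.0, 2000)
    y2 = rng.poisson(3.0, 2000)
    cohort = two_group_cohort(y1, y2)
    fit = hs.fit_two_part(cohort, "polyclinic", "broad_group", family="poisson")
    me = hs.marginal_effects(fit, cohort, n_boot=200, seed=5).set_index("group")
    mc_se = np.sqrt(3.0 / 2000 + 1.0 / 2000)
    assert abs(me.loc[ALT, "me"] - 2.0) < 3 * mc_se
    assert me.loc[ALT, "ci_low"] < 2.0 < me.loc[ALT, "ci_high"]


def test_delta_method_se_agrees_with_bootstrap():
    rng = np.random.default_rng(19)
    y1 = rng.poisson(1.0, 1500)
    y2 = rng.poisson(3.0, 1500)
    cohort = two_group_cohort(y1, y2)
    fit = hs.fit_two_part(cohort, "polyclinic", "broad_group", family="poisson")
    boot = hs.marginal_effects(fit, cohort, method="bootstrap", n_boot=400, seed=2)
    delta = hs.marginal_effects(fit, cohort, method="delta")
    sb = boot.set_index("group").loc[ALT, "se"]
    sd = delta.set_index("group").loc[ALT, "se"]
    assert 0.5 < sd / sb < 2.0
    assert delta.set_index("group").loc[ALT, "ci_low"] < 2.0 < delta.set_index("group").loc[ALT, "ci_high"]


def test_group_with_zero_users_flagged_not_estimable():
    rng = np.random.default_rng(30)
    df = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(900)],
            "segment": ["A"] * 300 + ["E"] * 300 + ["F"] * 300,
            "broad_group": [REF] * 300 + [ALT] * 600,
            "polyclinic": np.r_[rng.poisson(1.0, 300), rng.poisson(2.0, 300), np.zeros(300)],
            "icu": False,
            "died": False,
            "death_day": np.nan,
            "exposure": 1.0,
            "duration": 365.0,
            "event": False,
        }
    )
    cohort = ValidationCohort(2017, df)
    fit = hs.fit_two_part(cohort, "polyclinic", "segment", family="poisson")
    assert "F" not in fit.estimable
    me = hs.marginal_effects(fit, cohort, n_boot=20, seed=0).set_index("group")
    assert np.isnan(me.loc["F", "me"]) and not me.loc["F", "estimable"]


def test_family_selection_single_candidate_and_reporting(small_cohort):
    fit = hs.select_family(small_cohort, "bed_days", "broad_group", candidates=["gamma"])
    assert fit.family == "gamma"
    assert np.isfinite(fit.aic_per_obs)


def test_negbin_cannot_beat_poisson_much_on_equidispersed_counts():
    rng = np.random.default_rng(40)
    for _ in range(5):
        y1 = 1 + rng.poisson(1.5, 800)
        y2 = 1 + rng.poisson(3.0, 800)
        cohort = two_group_cohort(y1, y2)
        fit = hs.select_family(
            cohort, "polyclinic", "broad_group", candidates=["poisson", "negbin"]
        )
        aics = fit.family_aics
        # nested model: at most the parameter penalty separates them
        assert aics["poisson"] - aics["negbin"] <= 2.0 + 1e-6


# ---------------------------------------------------------------------------
# logistic odds ratios
# ---------------------------------------------------------------------------


def _icu_cohort(flags_by_group):
    frames = []
    for (seg, broad), flags in flags_by_group.items():
        frames.append(
            pd.DataFrame(
                {
                    "person_id": [f"{seg}{i}" for i in range(len(flags))],
                    "segment": seg,
                    "broad_group": broad,
                    "polyclinic": 0,
                    "icu": flags,
                    "died": False,
                    "death_day": np.nan,
                    "exposure": 1.0,
                    "duration": 365.0,
                    "event": False,
                }
            )
        )
    return ValidationCohort(2017, pd.concat(frames, ignore_index=True))


def test_reference_odds_ratio_is_exactly_one():
    rng = np.random.default_rng(6)
    cohort = _icu_cohort(
        {
            ("A", REF): rng.random(400) < 0.05,
            ("E", ALT): rng.random(400) < 0.15,
        }
    )
    out = hs.fit_logistic_or(cohort, "broad_group").set_index("group")
    assert out.loc[REF, "odds_ratio"] == 1.0


def test_identical_outcome_distributions_give_or_near_one():
    rng = np.random.default_rng(7)
    cohort = _icu_cohort(
        {
            ("A", REF): rng.random(3000) < 0.10,
            ("E", ALT): rng.random(3000) < 0.10,
        }
    )
    out = hs.fit_logistic_or(cohort, "broad_group").set_index("group")
    assert out.loc[ALT, "ci_low"] < 1.0 < out.loc[ALT, "ci_high"]


def test_degenerate_group_flagged_not_estimable():
    rng = np.random.default_rng(9)
    cohort = _icu_cohort(
        {
            ("A", REF): rng.random(300) < 0.10,
            ("E", ALT): rng.random(300) < 0.20,
            ("I", "getting_well"): np.zeros(300, bool),  # no ICU admissions at all
        }
    )
    out = hs.fit_logistic_or(cohort, "broad_group").set_index("group")
    assert not out.loc["getting_well", "estimable"]
    assert np.isnan(out.loc["getting_well", "odds_ratio"])


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def _survival_cohort(durations, events, labels):
    return ValidationCohort(
        2017,
        pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(len(durations))],
                "segment": ["E" if g == LIVING_WELL else "K" for g in labels],
                "broad_group": labels,
                "polyclinic": 0,
                "icu": False,
                "died": events,
                "death_day": np.where(events, durations, np.nan),
                "exposure": np.where(events, np.asarray(durations) / 365.0, 1.0),
                "duration": durations,
                "event": events,
            }
        ),
    )


def test_cox_matches_bruteforce_partial_likelihood_on_worked_dataset():
    durations = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([True, True, True, True])
    x = np.array([1.0, 0.0, 1.0, 0.0])
    labels = [MAXIMIZING if xi else LIVING_WELL for xi in x]
    cohort = _survival_cohort(durations, events, labels)

    def neg_log_pl(beta):
        # no ties: exact partial likelihood
        ll = 0.0
        order = np.argsort(durations)
        for idx, i in enumerate(order):
            risk = order[idx:]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    brute = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded")
    out = hs.fit_cox_hr(cohort, "broad_group", reference=LIVING_WELL).set_index("group")
    assert out.loc[MAXIMIZING, "hazard_ratio"] == pytest.approx(np.exp(brute.x), rel=1e-3)
    assert out.loc[LIVING_WELL, "hazard_ratio"] == 1.0


def test_identical_hazards_give_hr_near_one():
    rng = np.random.default_rng(14)
    n = 4000
    t = rng.exponential(1 / 0.004, n)
    events = t <= 365
    durations = np.minimum(t, 365.0)
    labels = np.where(np.arange(n) % 2 == 0, LIVING_WELL, MAXIMIZING)
    cohort = _survival_cohort(durations, events, labels)
    out = hs.fit_cox_hr(cohort, "broad_group", reference=LIVING_WELL).set_index("group")
    assert out.loc[MAXIMIZING, "ci_low"] < 1.0 < out.loc[MAXIMIZING, "ci_high"]


def test_child_segments_dropped_from_segment_level_survival():
    # needs enough persons that the simple-chronic reference segment has deaths
    cfg = hs.SyntheticConfig(n_persons=25_000, seed=13)
    pop = hs.generate_population(cfg)
    hs.generate_followup(pop, cfg)
    base = hs.apply_exclusions(pop.persons, cfg.year)
    feats = hs.assemble_person_year(base, pop.conditions, pop.programs)
    asg = hs.classify_population(feats)
    died = feats.loc[feats["died_in_year"], "person_id"]
    cohort = hs.build_cohort(asg, pop.followup, died_in_index_year=died)
    out = hs.fit_cox_hr(cohort, "segment")
    assert not set(out["group"]) & {"D", "I"}
    assert out.set_index("group").loc["E", "hazard_ratio"] == 1.0
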