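"""Prognostic validation models: two-part utilization, ICU odds, mortality.

The validation asks whether index-year segment membership predicts next-year
outcomes.  Persons segmented in the index year who survive it form the
cohort; those dying during the follow-up year contribute a partial-year
exposure (days alive / 365) entered as a log offset, so less opportunity for
utilization is accounted for.

* Visit/bed-day counts: two-part (hurdle) models — a logit-link GLM for any
  use and a log-link GLM for positive use, with the family of the second part
  (Poisson, Gamma, negative binomial, Gaussian) chosen by AIC.  Effects are
  reported as average marginal effects versus a reference group: the average
  change in predicted next-year utilization if a person's group were switched
  from the reference.
* ICU admission: logistic GLM, reported as odds ratios.
* Mortality: Cox proportional hazards on day of death within the follow-up
  year (censoring at day 365), Efron tie handling, reported as hazard ratios.

Reference conventions follow the least-needs-first convention for the
utilization and ICU models (staying-healthy broad group / mostly-healthy
segment) and, because deaths are rare there, the living-well-with-illness
group / simple-chronic segment for the survival models.  Child-only segments
are dropped from segment-level survival by default (deaths too rare).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.special import expit
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .segmentation import BROAD_GROUPS, LIVING_WELL, SEGMENTS, STAYING_HEALTHY

logger = logging.getLogger(__name__)

OUTCOMES = ("polyclinic", "specialist_outpatient", "emergency", "inpatient_acute", "bed_days")
FAMILIES = ("poisson", "gamma", "negbin", "gaussian")

DAYS_IN_YEAR = 365


def _levels_for(grouping: str) -> tuple[str, ...]:
    if grouping == "broad_group":
        return BROAD_GROUPS
    if grouping == "segment":
        return SEGMENTS
    raise ValueError(f"grouping must be 'broad_group' or 'segment', got {grouping!r}")


def default_reference(grouping: str, model: str = "utilization") -> str:
    """Least-needs reference for utilization/ICU; living-well tier for survival."""
    if model == "survival":
        return LIVING_WELL if grouping == "broad_group" else "E"
    return STAYING_HEALTHY if grouping == "broad_group" else "A"


@dataclass
class ValidationCohort:
    """Persons segmented in the index year and alive at its end."""

    year: int
    df: pd.DataFrame
    warnings: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)


def build_cohort(
    assignments: pd.DataFrame,
    followup: pd.DataFrame,
    died_in_index_year: Iterable[str] | None = None,
) -> ValidationCohort:
    """Join assignments with follow-up outcomes into the validation cohort.

    Index-year decedents are excluded (via ``died_in_index_year`` ids and/or
    absence of a follow-up row).  Exposure is the fraction of the follow-up
    year alive: ``death_day / 365`` for follow-up-year decedents, else 1.
    """
    warnings: dict[str, int] = {}
    dead_ids = set(died_in_index_year) if died_in_index_year is not None else set()

    fu = followup.copy()
    orphan = ~fu["person_id"].isin(assignments["person_id"])
    if orphan.any():
        warnings["followup_without_assignment"] = int(orphan.sum())
        logger.warning("%d follow-up record(s) without assignment excluded", int(orphan.sum()))
        fu = fu.loc[~orphan]

    df = assignments[["person_id", "segment", "broad_group"]].merge(fu, on="person_id", how="inner")
    n_no_fu = len(assignments) - len(df)
    if n_no_fu:
        warnings["assignment_without_followup"] = int(n_no_fu)
    if dead_ids:
        before = len(df)
        df = df.loc[~df["person_id"].isin(dead_ids)]
        warnings["index_year_deaths_excluded"] = before - len(df)

    died = df["died"].astype(bool).to_numpy()
    death_day = df["death_day"].to_numpy(float)
    df = df.assign(
        exposure=np.where(died, death_day / DAYS_IN_YEAR, 1.0),
        duration=np.where(died, death_day, float(DAYS_IN_YEAR)),
        event=died,
    )
    year = int(followup.attrs.get("year", 0)) if hasattr(followup, "attrs") else 0
    return ValidationCohort(year=year, df=df.reset_index(drop=True), warnings=warnings)


# ---------------------------------------------------------------------------
# Two-part models
# ---------------------------------------------------------------------------


@dataclass
class TwoPartFit:
    """Fitted hurdle model over group indicators with log-exposure offsets."""

    outcome: str
    grouping: str
    reference: str
    family: str
    levels: tuple[str, ...]
    estimable: tuple[str, ...]
    offset_parts: str
    part1_params: dict[str, float] | None  # None => every outcome positive
    part2_params: dict[str, float]
    aic: float
    aic_per_obs: float
    n_obs: int
    converged: bool
    part1_cov: np.ndarray | None = None
    part2_cov: np.ndarray | None = None
    family_aics: dict[str, float] | None = None

    def predict_mean(self, group: str, exposure: np.ndarray) -> np.ndarray:
        """Expected outcome E[y] = P(use) * E[y | use] at the given exposures."""
        if group not in self.estimable:
            return np.full(np.shape(exposure), np.nan)
        log_e = np.log(np.asarray(exposure, float))
        off1 = log_e if self.offset_parts in ("both", "part1") else 0.0
        off2 = log_e if self.offset_parts in ("both", "part2") else 0.0
        key = f"[{group}]"
        if self.part1_params is None:
            p = 1.0
        else:
            eta1 = self.part1_params["intercept"] + self.part1_params.get(key, 0.0)
            p = expit(eta1 + off1)
        eta2 = self.part2_params["intercept"] + self.part2_params.get(key, 0.0)
        return p * np.exp(eta2 + off2)


def _design(groups: pd.Series, levels: Sequence[str], reference: str):
    cols = [g for g in levels if g != reference and (groups == g).any()]
    X = np.column_stack(
        [np.ones(len(groups))] + [(groups == g).to_numpy(float) for g in cols]
    )
    return X, ["intercept"] + [f"[{g}]" for g in cols]


def _fit_part2(y, X, offset, family: str, names):
    if family == "negbin":
        model = NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        params = dict(zip(names, res.params[: len(names)]))
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        return params, float(res.aic), converged, cov
    fams = {
        "poisson": sm.families.Poisson(),
        "gamma": sm.families.Gamma(link=sm.families.links.Log()),
        "gaussian": sm.families.Gaussian(link=sm.families.links.Log()),
    }
    model = sm.GLM(y, X, family=fams[family], offset=offset)
    try:
        res = model.fit()
    except Exception:
        start = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit().params
        res = model.fit(start_params=start)
    params = dict(zip(names, res.params))
    return params, float(res.aic), True, np.asarray(res.cov_params())


def fit_two_part(
    cohort: ValidationCohort,
    outcome: str,
    grouping: str = "broad_group",
    reference: str | None = None,
    family: str = "poisson",
    offset_parts: str = "both",
) -> TwoPartFit:
    """Fit the hurdle model for one count outcome over group indicators.

    Part 1 is a logit-link GLM of any use; part 2 a log-link GLM of positive
    use under ``family``.  The log of exposure enters as an offset in both
    parts by default (``offset_parts`` may restrict it to one part).  Groups
    with no positive outcomes are flagged inestimable rather than failing.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if offset_parts not in ("both", "part1", "part2"):
        raise ValueError("offset_parts must be 'both', 'part1' or 'part2'")
    levels = _levels_for(grouping)
    reference = reference or default_reference(grouping)
    df = cohort.df
    y = df[outcome].to_numpy(float)
    if (y < 0).any():
        raise ValueError(f"{outcome}: negative outcome values")
    groups = df[grouping]
    log_e = np.log(df["exposure"].to_numpy(float))

    present = [g for g in levels if (groups == g).any()]
    positive = y > 0
    with_pos = {g for g in present if (positive & (groups == g)).any()}
    if reference not in with_pos:
        raise ValueError(f"reference group {reference!r} has no positive outcomes")
    estimable = tuple(g for g in present if g in with_pos)

    # Part 1: any use.  Collapses to P(use)=1 when no zeros exist.
    part1_params = part1_cov = None
    if not positive.all():
        X1, names1 = _design(groups, levels, reference)
        off1 = log_e if offset_parts in ("both", "part1") else None
        res1 = sm.GLM(positive.astype(float), X1, family=sm.families.Binomial(), offset=off1).fit()
        part1_params = dict(zip(names1, res1.params))
        part1_cov = np.asarray(res1.cov_params())

    # Part 2: positive use, restricted to estimable groups.
    sub = positive & groups.isin(estimable).to_numpy()
    X2, names2 = _design(groups.loc[sub].reset_index(drop=True), levels, reference)
    off2 = log_e[sub] if offset_parts in ("both", "part2") else None
    part2_params, aic, converged, part2_cov = _fit_part2(y[sub], X2, off2, family, names2)
    n2 = int(sub.sum())

    return TwoPartFit(
        outcome=outcome,
        grouping=grouping,
        reference=reference,
        family=family,
        levels=tuple(present),
        estimable=estimable,
        offset_parts=offset_parts,
        part1_params=part1_params,
        part2_params=part2_params,
        aic=aic,
        aic_per_obs=aic / n2,
        n_obs=n2,
        converged=converged,
        part1_cov=part1_cov,
        part2_cov=part2_cov,
    )


def select_family(
    cohort: ValidationCohort,
    outcome: str,
    grouping: str = "broad_group",
    reference: str | None = None,
    candidates: Sequence[str] = FAMILIES,
    offset_parts: str = "both",
) -> TwoPartFit:
    """Fit each candidate family for part 2 and return the AIC minimizer.

    Ties break in candidate order.  If every candidate fails, raises with
    each failure named.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    fits: dict[str, TwoPartFit] = {}
    aics: dict[str, float] = {}
    failures: dict[str, str] = {}
    for fam in candidates:
        try:
            fit = fit_two_part(cohort, outcome, grouping, reference, fam, offset_parts)
            fits[fam] = fit
            aics[fam] = fit.aic
        except (ValueError, np.linalg.LinAlgError, RuntimeError) as exc:
            failures[fam] = str(exc)
    if not fits:
        raise RuntimeError(f"all candidate families failed: {failures}")
    best = min(fits, key=lambda f: (aics[f], list(candidates).index(f)))
    chosen = fits[best]
    chosen.family_aics = aics
    return chosen


def _point_me(fit: TwoPartFit, exposure: np.ndarray) -> dict[str, float]:
    ref_pred = fit.predict_mean(fit.reference, exposure)
    out = {}
    for g in fit.levels:
        if g == fit.reference:
            out[g] = 0.0
        elif g in fit.estimable:
            out[g] = float(np.mean(fit.predict_mean(g, exposure) - ref_pred))
        else:
            out[g] = float("nan")
    return out


def _fast_bootstrap_draws(y, gcodes, n_groups, ref_code, B, rng):
    """Bootstrap ME draws for saturated group-only fits at unit exposure.

    For log-link Poisson/Gamma/NB2 part 2 with group indicators only, the
    fitted two-part mean per group is the group sample mean, so each
    resample's refit reduces to group means of the resampled data.
    """
    n = len(y)
    draws = np.empty((B, n_groups))
    for b in range(B):
        idx = rng.integers(0, n, n)
        gs = gcodes[idx]
        ys = y[idx]
        cnt = np.bincount(gs, minlength=n_groups).astype(float)
        sums = np.bincount(gs, weights=ys, minlength=n_groups)
        with np.errstate(invalid="ignore"):
            means = sums / cnt
        draws[b] = means - means[ref_code]
    return draws


def marginal_effects(
    fit: TwoPartFit,
    cohort: ValidationCohort,
    method: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Average marginal effects per group versus the reference, with 95% CI.

    ME_g averages, over the cohort's observed exposures, the difference in
    predicted outcome between membership in g and in the reference.  CIs are
    nonparametric (persons resampled) percentile bootstrap by default, with a
    numeric-gradient delta-method alternative.  The reference row is exactly
    zero with a degenerate CI.
    """
    df = cohort.df
    exposure = df["exposure"].to_numpy(float)
    point = _point_me(fit, exposure)
    groups = list(fit.levels)

    if method == "delta":
        se = _delta_se(fit, exposure)
    elif method == "bootstrap":
        se = None
    else:
        raise ValueError("method must be 'bootstrap' or 'delta'")

    rows = []
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        gseries = df[fit.grouping]
        codes_map = {g: i for i, g in enumerate(groups)}
        y = df[fit.outcome].to_numpy(float)
        fast = (
            np.allclose(exposure, 1.0)
            and fit.family in ("poisson", "gamma", "negbin")
        )
        if fast:
            gcodes = gseries.map(codes_map).to_numpy()
            draws = _fast_bootstrap_draws(
                y, gcodes, len(groups), codes_map[fit.reference], n_boot, rng
            )
        else:
            draws = np.full((n_boot, len(groups)), np.nan)
            for b in range(n_boot):
                idx = rng.integers(0, len(df), len(df))
                boot = ValidationCohort(cohort.year, df.iloc[idx].reset_index(drop=True))
                try:
                    bfit = fit_two_part(
                        boot, fit.outcome, fit.grouping, fit.reference,
                        fit.family, fit.offset_parts,
                    )
                except (ValueError, np.linalg.LinAlgError):
                    continue
                bme = _point_me(bfit, boot.df["exposure"].to_numpy(float))
                draws[b] = [bme.get(g, np.nan) for g in groups]
        for i, g in enumerate(groups):
            if g == fit.reference:
                rows.append((g, 0.0, 0.0, 0.0, 0.0, np.nan, True))
                continue
            if g not in fit.estimable:
                rows.append((g, np.nan, np.nan, np.nan, np.nan, np.nan, False))
                continue
            d = draws[:, i]
            d = d[np.isfinite(d)]
            lo, hi = np.percentile(d, [2.5, 97.5])
            s = float(d.std(ddof=1))
            p = 2 * norm.sf(abs(point[g]) / s) if s > 0 else np.nan
            rows.append((g, point[g], lo, hi, s, p, True))
    else:
        for g in groups:
            if g == fit.reference:
                rows.append((g, 0.0, 0.0, 0.0, 0.0, np.nan, True))
            elif g not in fit.estimable:
                rows.append((g, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            else:
                s = se[g]
                z = norm.ppf(0.975)
                p = 2 * norm.sf(abs(point[g]) / s) if s > 0 else np.nan
                rows.append((g, point[g], point[g] - z * s, point[g] + z * s, s, p, True))

    return pd.DataFrame(
        rows, columns=["group", "me", "ci_low", "ci_high", "se", "p_value", "estimable"]
    )


def _delta_se(fit: TwoPartFit, exposure: np.ndarray) -> dict[str, float]:
    """Delta-method SEs from a numeric gradient of the ME map."""
    p1 = fit.part1_params or {}
    names1 = list(p1)
    names2 = list(fit.part2_params)
    theta0 = np.array([p1[k] for k in names1] + [fit.part2_params[k] for k in names2])

    def me_vec(theta):
        f = TwoPartFit(
            **{
                **fit.__dict__,
                "part1_params": dict(zip(names1, theta[: len(names1)])) if names1 else None,
                "part2_params": dict(zip(names2, theta[len(names1):])),
            }
        )
        me = _point_me(f, exposure)
        return np.array([me[g] for g in fit.levels])

    eps = 1e-6
    J = np.empty((len(fit.levels), len(theta0)))
    base = me_vec(theta0)
    for j in range(len(theta0)):
        step = np.zeros_like(theta0)
        step[j] = eps
        J[:, j] = (me_vec(theta0 + step) - base) / eps
    blocks = []
    if names1:
        blocks.append(fit.part1_cov)
    blocks.append(fit.part2_cov)
    V = np.zeros((len(theta0), len(theta0)))
    i = 0
    for b in blocks:
        k = b.shape[0]
        V[i : i + k, i : i + k] = b
        i += k
    var = np.einsum("ij,jk,ik->i", J, V, J)
    return {g: float(np.sqrt(max(v, 0.0))) for g, v in zip(fit.levels, var)}


# ---------------------------------------------------------------------------
# ICU logistic odds ratios
# ---------------------------------------------------------------------------


def fit_logistic_or(
    cohort: ValidationCohort,
    grouping: str = "broad_group",
    reference: str | None = None,
    outcome: str = "icu",
) -> pd.DataFrame:
    """Logit-link binomial GLM of next-year ICU admission on group indicators.

    Returns per-group odds ratios with Wald 95% CIs; the reference row is
    exactly 1.  Groups whose outcomes are all 0 or all 1 are flagged
    nonestimable and excluded from the fit.
    """
    levels = _levels_for(grouping)
    reference = reference or default_reference(grouping)
    df = cohort.df
    y = df[outcome].astype(bool)
    if y.all() or (~y).all():
        raise ValueError("both outcome classes must be present overall")
    groups = df[grouping]
    present = [g for g in levels if (groups == g).any()]
    estimable = [
        g
        for g in present
        if 0 < int(y[groups == g].sum()) < int((groups == g).sum())
    ]
    if reference not in estimable:
        raise ValueError(f"reference group {reference!r} has a degenerate outcome")

    keep = groups.isin(estimable).to_numpy()
    gk = groups.loc[keep].reset_index(drop=True)
    X, names = _design(gk, levels, reference)
    res = sm.GLM(y.to_numpy(float)[keep], X, family=sm.families.Binomial()).fit()
    coefs = dict(zip(names, res.params))
    ci = res.conf_int()
    cis = {name: tuple(ci[i]) for i, name in enumerate(names)}
    pvals = dict(zip(names, res.pvalues))

    rows = []
    for g in present:
        if g == reference:
            rows.append((g, 1.0, 1.0, 1.0, np.nan, True))
        elif g in estimable:
            key = f"[{g}]"
            lo, hi = cis[key]
            rows.append((g, float(np.exp(coefs[key])), float(np.exp(lo)), float(np.exp(hi)), float(pvals[key]), True))
        else:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["group", "odds_ratio", "ci_low", "ci_high", "p_value", "estimable"]
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards for next-year mortality
# ---------------------------------------------------------------------------

#: Child-only segments dropped from segment-level survival by default.
DEFAULT_SURVIVAL_DROP = ("D", "I")


def fit_cox_hr(
    cohort: ValidationCohort,
    grouping: str = "broad_group",
    reference: str | None = None,
    drop_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cox model of follow-up-year mortality on group indicators only.

    Durations are days 1-365 with censoring at 365; ties use the Efron
    approximation.  Hazard ratios are relative to the living-well tier by
    default.  Groups with zero deaths are flagged degenerate and excluded.
    """
    levels = _levels_for(grouping)
    reference = reference or default_reference(grouping, model="survival")
    if drop_groups is None:
        drop_groups = DEFAULT_SURVIVAL_DROP if grouping == "segment" else ()
    df = cohort.df
    groups = df[grouping]
    present = [g for g in levels if (groups == g).any() and g not in set(drop_groups)]
    deaths = {g: int(df.loc[groups == g, "event"].sum()) for g in present}
    estimable = [g for g in present if deaths[g] > 0]
    if reference not in estimable:
        raise ValueError(f"survival reference {reference!r} has no deaths")

    keep = groups.isin(estimable).to_numpy()
    gk = groups.loc[keep].reset_index(drop=True)
    X, names = _design(gk, levels, reference)
    data = pd.DataFrame(X[:, 1:], columns=names[1:])
    data["duration"] = df.loc[keep, "duration"].to_numpy()
    data["event"] = df.loc[keep, "event"].to_numpy(bool)
    # Newton can overshoot (or stall at a poor point) when a group's hazard
    # contrast is very large (log-HR of 4+).  Fit over a small ladder of step
    # sizes and keep the solution with the highest partial log-likelihood.
    best: CoxPHFitter | None = None
    last_exc: Exception | None = None
    for step_size in (None, 0.1, 0.05):
        opts = {"step_size": step_size} if step_size else None
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col="duration", event_col="event", fit_options=opts)
        except Exception as exc:  # ConvergenceError / LinAlgError
            last_exc = exc
            continue
        if best is None or cph.log_likelihood_ > best.log_likelihood_ + 1e-8:
            best = cph
    if best is None:
        raise RuntimeError(f"Cox fit failed to converge: {last_exc}")
    summ = best.summary  # Efron ties (lifelines default)

    rows = []
    for g in present:
        if g == reference:
            rows.append((g, 1.0, 1.0, 1.0, np.nan, True, deaths[g]))
        elif g in estimable:
            r = summ.loc[f"[{g}]"]
            rows.append(
                (g, float(r["exp(coef)"]), float(r["exp(coef) lower 95%"]),
                 float(r["exp(coef) upper 95%"]), float(r["p"]), True, deaths[g])
            )
        else:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, False, deaths[g]))
    return pd.DataFrame(
        rows,
        columns=["group", "hazard_ratio", "ci_low", "ci_high", "p_value", "estimable", "deaths"],
    )
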