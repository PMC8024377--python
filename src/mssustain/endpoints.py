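"""Clinical endpoint definitions and subtype/stage association analyses.

Implements the trial-style endpoints used to characterise MRI-based
subtypes: 24-week confirmed disability progression (CDP) from EDSS series,
log-rank and Cox contrasts of time-to-CDP, baseline-stage tertile
stratification, annualized relapse rates, Harrell's concordance index,
EDSS-slope treatment response from a linear mixed model, annual change in
model stage, and within-subject subtype stability.

EDSS is the Expanded Disability Status Scale (0-10 in 0.5 steps, higher =
worse).  A CDP event requires an EDSS increase over baseline of at least
1.5 points (baseline 0), 1.0 point (baseline 0.5-5.5) or 0.5 points
(baseline > 5.5), sustained at every subsequent visit up to and including
the first visit at least 24 weeks (168 days) later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "edss_increase_threshold",
    "detect_cdp",
    "cdp_survival_table",
    "logrank_compare",
    "hazard_contrast",
    "stage_tertiles",
    "annualized_relapse_rate",
    "concordance_index",
    "treatment_response",
    "annual_stage_change",
    "subtype_stability",
]

DAYS_PER_YEAR = 365.25

_EDSS_LATTICE_TOL = 1e-9


def _check_edss(value: float) -> None:
    if not 0.0 <= value <= 10.0 or abs(value * 2 - round(value * 2)) > _EDSS_LATTICE_TOL:
        raise ValueError(f"EDSS {value} is off the 0.5-point lattice in [0, 10]")


def edss_increase_threshold(baseline_edss: float) -> float:
    """Minimum EDSS increase that counts as disability progression.

    1.5 points from a baseline of 0; 1.0 point from 0.5-5.5; 0.5 points
    above 5.5.
    """
    _check_edss(baseline_edss)
    if baseline_edss == 0.0:
        return 1.5
    if baseline_edss <= 5.5:
        return 1.0
    return 0.5


def detect_cdp(times_days, edss, confirm_days: float = 168.0,
               require_all_interim: bool = True) -> tuple[bool, float]:
    """Scan one subject's EDSS series for 24-week confirmed progression.

    ``times_days`` are visit times in days from baseline (strictly
    increasing); baseline EDSS is the first visit's value.  A candidate
    onset qualifies if its EDSS increase over baseline meets the threshold
    and the increase is sustained up to and including the first visit at
    least ``confirm_days`` later (all interim visits must also meet the
    threshold unless ``require_all_interim`` is False).  Returns
    ``(event, time_days)`` — the earliest qualifying onset, else censoring
    at the last visit.
    """
    t = np.asarray(times_days, dtype=float)
    e = np.asarray(edss, dtype=float)
    if t.size < 2:
        return False, float(t[-1]) if t.size else 0.0
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit times must be strictly increasing")
    thr = edss_increase_threshold(e[0])
    worse = e - e[0] >= thr
    for i in range(1, t.size):
        if not worse[i]:
            continue
        later = np.nonzero(t >= t[i] + confirm_days)[0]
        if later.size == 0:
            continue  # unconfirmable candidate
        j = later[0]
        window = worse[i + 1 : j + 1] if require_all_interim else worse[j : j + 1]
        if window.size and window.all():
            return True, float(t[i])
    return False, float(t[-1])


def cdp_survival_table(cohort: pd.DataFrame, confirm_days: float = 168.0,
                       groups: pd.Series | dict | None = None) -> pd.DataFrame:
    """One survival record per subject from a long-format cohort table.

    Columns: subject_id, time (years from baseline), event, baseline_edss,
    plus age/sex at baseline and an optional ``group`` label.
    """
    recs = []
    for sid, sub in cohort.sort_values("visit_time").groupby("subject_id",
                                                             sort=False):
        e = sub["edss"].to_numpy(dtype=float)
        if np.all(np.isnan(e)) or len(sub) < 2:
            continue
        t_days = sub["visit_time"].to_numpy(dtype=float) * DAYS_PER_YEAR
        event, t_ev = detect_cdp(t_days, e, confirm_days)
        rec = {
            "subject_id": sid,
            "time": t_ev / DAYS_PER_YEAR,
            "event": bool(event),
            "baseline_edss": e[0],
        }
        for c in ("age", "sex", "arm", "dataset_id"):
            if c in sub.columns:
                rec[c] = sub[c].iloc[0]
        recs.append(rec)
    out = pd.DataFrame(recs)
    if groups is not None and len(out):
        g = pd.Series(groups)
        out["group"] = out["subject_id"].map(g).to_numpy()
    return out


def logrank_compare(records: pd.DataFrame, group_col: str = "group"):
    """k-group log-rank test on CDP survival records.

    Returns (chi-square statistic, two-sided p-value) with k-1 degrees of
    freedom; delegates to lifelines.
    """
    from lifelines.statistics import multivariate_logrank_test

    if records["event"].sum() == 0:
        raise ValueError("all records censored; log-rank undefined")
    if records[group_col].nunique() < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(
        records["time"], records[group_col], records["event"])
    return float(res.test_statistic), float(res.p_value)


def hazard_contrast(records: pd.DataFrame, reference_group,
                    group_col: str = "group", covariates=()) -> pd.DataFrame:
    """Cox proportional-hazards contrasts of each group versus a reference.

    Returns a frame indexed by group with hazard ratio, 95% CI and Wald p.
    Warns when there are fewer than 10 events per fitted parameter.
    """
    from lifelines import CoxPHFitter

    groups = [g for g in pd.unique(records[group_col]) if g != reference_group]
    X = pd.DataFrame({"time": records["time"].astype(float),
                      "event": records["event"].astype(int)})
    for g in groups:
        X[f"grp_{g}"] = (records[group_col] == g).astype(float).to_numpy()
    for c in covariates:
        X[c] = records[c].astype(float).to_numpy()
    n_params = len(groups) + len(covariates)
    if records["event"].sum() < 10 * n_params:
        warnings.warn("fewer than 10 events per fitted parameter",
                      stacklevel=2)
    cph = CoxPHFitter()
    cph.fit(X, duration_col="time", event_col="event")
    rows = []
    for g in groups:
        name = f"grp_{g}"
        hr = float(np.exp(cph.params_[name]))
        lo, hi = np.exp(cph.confidence_intervals_.loc[name])
        rows.append({"group": g, "hazard_ratio": hr,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "p": float(cph.summary.loc[name, "p"])})
    return pd.DataFrame(rows).set_index("group")


def stage_tertiles(stages) -> tuple[np.ndarray, tuple[float, float]]:
    """Empirical tertile labels (0 low / 1 middle / 2 high) for baseline
    stages; ties at a cutpoint go to the lower group.

    Returns (labels, (cut1, cut2)); cuts are inverted-CDF empirical
    tertiles, so 39 uniformly occupied stages cut at 13 and 26.
    """
    s = np.asarray(stages, dtype=float)
    if s.size == 0:
        raise ValueError("empty stage list")
    if np.unique(s).size < 3:
        raise ValueError("fewer than 3 distinct stage values")
    c1, c2 = np.quantile(s, [1 / 3, 2 / 3], method="inverted_cdf")
    labels = np.where(s <= c1, 0, np.where(s <= c2, 1, 2))
    return labels, (float(c1), float(c2))


def annualized_relapse_rate(cohort: pd.DataFrame, groups: pd.Series | dict,
                            ) -> pd.DataFrame:
    """Relapses per person-year per group, with Poisson-regression SEs.

    Sums ``relapses_since_last_visit`` over follow-up and divides by
    person-years (last minus first visit time); the SE comes from an
    intercept-only Poisson GLM with a log person-years offset fitted per
    group (delta method on the rate scale).
    """
    import statsmodels.api as sm

    g = pd.Series(groups)
    per_subj = []
    for sid, sub in cohort.groupby("subject_id", sort=False):
        py = sub["visit_time"].max() - sub["visit_time"].min()
        count = sub["relapses_since_last_visit"].dropna().sum()
        per_subj.append({"subject_id": sid, "person_years": py,
                         "relapses": count})
    tab = pd.DataFrame(per_subj)
    tab["group"] = tab["subject_id"].map(g).to_numpy()
    tab = tab.dropna(subset=["group"])
    rows = []
    for grp, sub in tab.groupby("group"):
        py = sub["person_years"].sum()
        if py <= 0:
            raise ValueError(f"zero person-years in group {grp}")
        count = sub["relapses"].sum()
        rate = count / py
        if count == 0:
            se = 0.0
        else:
            glm = sm.GLM(sub["relapses"].to_numpy(),
                         np.ones((len(sub), 1)),
                         family=sm.families.Poisson(),
                         offset=np.log(sub["person_years"].to_numpy()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = glm.fit()
            se = float(rate * fit.bse[0])  # delta method: d(e^b)/db = e^b
        rows.append({"group": grp, "rate": float(rate), "se": se,
                     "relapses": float(count), "person_years": float(py)})
    return pd.DataFrame(rows).set_index("group")


def concordance_index(risk_scores, times, events=None) -> float:
    """Harrell's c-index over censoring-comparable pairs.

    A pair is comparable when the smaller time is an event; it is
    concordant when the higher risk score has the shorter time; risk ties
    count one half.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = (np.ones_like(t, dtype=bool) if events is None
         else np.asarray(events, dtype=bool))
    if not (r.size == t.size == e.size):
        raise ValueError("inputs must have equal length")
    num = den = 0.0
    for i in range(t.size):
        if not e[i]:
            continue
        comparable = (t > t[i]) | ((t == t[i]) & ~e)
        den += comparable.sum()
        num += (r[comparable] < r[i]).sum() + 0.5 * (r[comparable] == r[i]).sum()
    if den == 0:
        raise ValueError("no comparable pairs")
    return float(num / den)


@dataclass
class TreatmentResponse:
    """Percentage change in EDSS-worsening slope, treated versus placebo."""

    percent_change: float
    se: float
    slope_placebo: float
    slope_treated: float
    p_interaction: float
    defined: bool = True


def treatment_response(
    edss_long: pd.DataFrame,
    arm_col: str = "arm",
    time_col: str = "visit_time",
    subject_col: str = "subject_id",
    min_placebo_slope: float = 0.01,
) -> TreatmentResponse:
    """Mixed-model treatment response for one stratum (e.g. one subtype).

    Fits EDSS ~ arm + time + arm:time with a random intercept per subject
    and reports 100 * (slope_treated - slope_placebo) / slope_placebo with
    a delta-method SE.  Requires both arms; flags the response undefined
    when the placebo slope is within ``min_placebo_slope`` of zero.
    """
    import statsmodels.formula.api as smf

    df = edss_long.dropna(subset=["edss"]).copy()
    arms = set(df[arm_col].unique())
    if not {"placebo", "treated"} <= arms:
        raise ValueError("both placebo and treated arms required")
    df["treated"] = (df[arm_col] == "treated").astype(float)
    df = df.rename(columns={time_col: "t_years"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("edss ~ treated + t_years + treated:t_years",
                          df, groups=df[subject_col]).fit(reml=True)
    b_time = float(fit.params["t_years"])
    b_int = float(fit.params["treated:t_years"])
    cov = fit.cov_params().loc[["t_years", "treated:t_years"],
                               ["t_years", "treated:t_years"]].to_numpy()
    if abs(b_time) < min_placebo_slope:
        return TreatmentResponse(np.nan, np.nan, b_time, b_time + b_int,
                                 float(fit.pvalues["treated:t_years"]),
                                 defined=False)
    pct = 100.0 * b_int / b_time
    grad = np.array([-100.0 * b_int / b_time**2, 100.0 / b_time])
    se = float(np.sqrt(grad @ cov @ grad))
    return TreatmentResponse(
        percent_change=float(pct), se=se, slope_placebo=b_time,
        slope_treated=b_time + b_int,
        p_interaction=float(fit.pvalues["treated:t_years"]))


def annual_stage_change(staged: pd.DataFrame, groups: pd.Series | dict,
                        stage_col: str = "expected_stage",
                        ) -> pd.DataFrame:
    """Per-group mean of per-subject least-squares stage-versus-time slopes.

    Subjects need at least two staged visits; SE is the standard error of
    the per-subject slopes within each group.
    """
    g = pd.Series(groups)
    slopes = {}
    for sid, sub in staged.groupby("subject_id", sort=False):
        t = sub["visit_time"].to_numpy(dtype=float)
        y = sub[stage_col].to_numpy(dtype=float)
        if len(sub) < 2 or np.ptp(t) == 0:
            continue
        slopes[sid] = np.polyfit(t, y, 1)[0]
    if not slopes:
        raise ValueError("no subject has two or more staged visits")
    tab = pd.DataFrame({"slope": pd.Series(slopes)})
    tab["group"] = tab.index.map(g).to_numpy()
    tab = tab.dropna(subset=["group"])
    rows = []
    for grp, sub in tab.groupby("group"):
        rows.append({
            "group": grp,
            "slope": float(sub["slope"].mean()),
            "se": float(sub["slope"].std(ddof=1) / np.sqrt(len(sub)))
            if len(sub) > 1 else np.nan,
            "n": len(sub),
        })
    return pd.DataFrame(rows).set_index("group")


def subtype_stability(assignments: pd.DataFrame,
                      subtype_col: str = "modal_subtype") -> float:
    """Fraction of multi-visit subjects whose modal subtype never changes."""
    counts = assignments.groupby("subject_id", sort=False)[subtype_col].agg(
        ["nunique", "size"])
    multi = counts[counts["size"] >= 2]
    if len(multi) == 0:
        raise ValueError("no subject has two or more visits")
    return float((multi["nunique"] == 1).mean())
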