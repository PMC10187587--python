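"""Survival estimation and inference for the cohort analyses.

Wraps the standard machinery: Kaplan-Meier with Greenwood variance and
complementary-log-log confidence intervals, the log-rank test, Cox
proportional-hazards regression (Efron tie handling) in the two model
specifications used downstream (imaging-group model and PTC-per-10% model),
Aalen-Johansen cumulative incidence, and a Fine-Gray subdistribution-hazard
fit implemented through censoring-weighted (IPCW) risk-set expansion.

Follow-up is measured in months from diagnosis; rows with 0-month follow-up
(death in the diagnosis month) are excluded by :func:`apply_exclusions`
before modelling, with an option to re-include them at a half-month for the
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

CAUSES = ("hcc_death", "other_death", "censored")


class ConvergenceError(RuntimeError):
    pass


def apply_exclusions(
    dataset: pd.DataFrame,
    include_zero_month: bool = False,
    zero_month_value: float = 0.5,
    time_col: str = "time_months",
) -> tuple[pd.DataFrame, int]:
    """Apply the 0-month follow-up exclusion.

    Rows with ``time == 0`` (death or loss in the diagnosis month) are
    removed, and the number of removals returned. With
    ``include_zero_month=True`` (the sensitivity analysis) those rows are
    instead retained with their time remapped to ``zero_month_value``
    (default half a month).
    """
    zero = dataset[time_col].to_numpy() == 0
    n_zero = int(zero.sum())
    out = dataset.copy()
    if include_zero_month:
        out.loc[zero, time_col] = zero_month_value
        return out, 0
    return out.loc[~zero].reset_index(drop=True), n_zero


@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood variance and cloglog CIs."""

    table: pd.DataFrame  # time, at_risk, events, censored, survival, variance, ci_low, ci_high
    median: float  # NaN when survival never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S(t) (right-continuous)."""
        times = self.table["time"].to_numpy(float)
        surv = self.table["survival"].to_numpy(float)
        idx = np.searchsorted(times, np.atleast_1d(np.asarray(t, float)), side="right")
        out = np.where(idx == 0, 1.0, surv[np.maximum(idx - 1, 0)])
        return out

    @property
    def median_defined(self) -> bool:
        return bool(np.isfinite(self.median))


def km_estimate(times, events, ci_level: float = 0.95) -> KMEstimate:
    """Kaplan-Meier estimate of the survival function.

    Returns the full step table (numbers at risk, deaths, Greenwood variance,
    complementary-log-log confidence bounds) plus the median with its CI.
    An undefined median (survival never reaching 0.5) is flagged as NaN, not
    raised.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    if np.any(times <= 0):
        raise ValueError("times must be > 0; run apply_exclusions first")
    kmf = KaplanMeierFitter(alpha=1 - ci_level)
    kmf.fit(times, events)
    ev = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    grid = ev.index.to_numpy(float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    d = ev["observed"].to_numpy(float)
    n_r = ev["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_r > d, d / (n_r * (n_r - d)), np.nan)
    variance = surv**2 * np.cumsum(gw_terms)
    ci = kmf.confidence_interval_survival_function_
    ci_at = ci.reindex(ci.index.union(grid)).ffill().loc[grid]
    table = pd.DataFrame(
        {
            "time": grid,
            "at_risk": n_r.astype(int),
            "events": d.astype(int),
            "censored": ev["censored"].to_numpy(int),
            "survival": surv,
            "variance": variance,
            "ci_low": ci_at.iloc[:, 0].to_numpy(),
            "ci_high": ci_at.iloc[:, 1].to_numpy(),
        }
    )
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    med_lo, med_hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    return KMEstimate(
        table=table,
        median=median,
        median_ci=(med_lo, med_hi),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_test(times, events, group_labels) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi_square, df, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(group_labels)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


@dataclass
class ModelResult:
    """Tidy proportional-hazards fit: one row per term plus metadata."""

    terms: pd.DataFrame  # term, coef, se, hr, ci_low, ci_high, p
    model_id: str
    n: int
    n_events: int
    dropped_terms: list[str] = field(default_factory=list)

    def hr(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "hr"])

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["model_id"] = self.model_id
        out["n"] = self.n
        out["n_events"] = self.n_events
        return out


def _design_matrix(
    dataset: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Expand categorical covariates to treatment-coded dummies.

    The imaging ``group`` column is coded against the "none" reference;
    other categoricals drop their most frequent level. Constant columns are
    dropped and reported (flagged, not fatal)."""
    cols = []
    for cov in covariates:
        s = dataset[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(s))
            if cov == "group":
                ref = "none"
                order = [g for g in ("none", "ultrasound", "ctmri") if g in levels]
            else:
                ref = s.mode().iloc[0]
                order = sorted(levels, key=str)
            for lev in order:
                if lev == ref:
                    continue
                cols.append(pd.Series((s == lev).astype(float), name=f"{cov}[{lev}]"))
        else:
            cols.append(s.astype(float).rename(cov))
    X = pd.concat(cols, axis=1)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    return X.drop(columns=dropped), dropped


def fit_cox(
    dataset: pd.DataFrame,
    specification: str = "custom",
    covariates: list[str] | None = None,
    time_col: str = "time_months",
    event_col: str = "event",
    ci_level: float = 0.95,
) -> ModelResult:
    """Cox proportional-hazards fit (Efron ties) in one of the study's two
    specifications, or with a custom covariate list.

    ``specification="group_model"`` enters the imaging group (reference: no
    imaging); ``"ptc_model"`` enters PTC by ultrasound and by CT/MRI jointly,
    rescaled so one unit is 10 percentage points of coverage (columns
    ``ptc_us`` / ``ptc_ctmri`` on the [0, 1] scale are expected).
    """
    df = dataset.copy()
    covariates = list(covariates) if covariates else []
    if specification == "group_model":
        covariates = ["group"] + [c for c in covariates if c != "group"]
    elif specification == "ptc_model":
        df["ptc_us_per10"] = df["ptc_us"] * 10.0
        df["ptc_ctmri_per10"] = df["ptc_ctmri"] * 10.0
        covariates = ["ptc_us_per10", "ptc_ctmri_per10"] + [
            c for c in covariates if not c.startswith("ptc")
        ]
    elif specification != "custom":
        raise ValueError(f"unknown specification {specification!r}")
    if not covariates:
        raise ValueError("no covariates to fit")
    X, dropped = _design_matrix(df, covariates)
    if X.shape[1] == 0:
        raise ValueError("all covariates are constant; nothing to fit")
    fit_df = pd.concat(
        [df[[time_col, event_col]].reset_index(drop=True), X.reset_index(drop=True)],
        axis=1,
    )
    cph = CoxPHFitter(alpha=1 - ci_level)
    try:
        cph.fit(fit_df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    return _tidy_from_lifelines(cph, specification, len(fit_df),
                                int(fit_df[event_col].sum()), dropped)


def _tidy_from_lifelines(
    fitter, model_id: str, n: int, n_events: int, dropped: list[str]
) -> ModelResult:
    summ = fitter.summary
    terms = pd.DataFrame(
        {
            "term": summ.index.get_level_values(-1),
            "coef": summ["coef"].to_numpy(),
            "se": summ["se(coef)"].to_numpy(),
            "hr": np.exp(summ["coef"].to_numpy()),
            "ci_low": np.exp(summ.filter(like="coef lower").iloc[:, 0].to_numpy()),
            "ci_high": np.exp(summ.filter(like="coef upper").iloc[:, 0].to_numpy()),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return ModelResult(terms=terms, model_id=model_id, n=n, n_events=n_events,
                       dropped_terms=dropped)


def cumulative_incidence(
    times, causes, cause_col_values: tuple[str, ...] = ("hcc_death", "other_death")
) -> dict[str, pd.DataFrame]:
    """Aalen-Johansen cumulative incidence per cause.

    ``causes`` holds one of {"hcc_death", "other_death", "censored"} per
    subject. Returns cause -> DataFrame(time, cif). With a single failure
    cause present, the CIF reduces exactly to 1 - KM survival.
    """
    times = np.asarray(times, float)
    causes = np.asarray(causes)
    bad = set(np.unique(causes)) - set(CAUSES)
    if bad:
        raise ValueError(f"unknown causes {sorted(bad)}")
    event_code = np.zeros(times.size, dtype=int)
    for k, c in enumerate(cause_col_values, start=1):
        event_code[causes == c] = k
    out: dict[str, pd.DataFrame] = {}
    grid = np.unique(times)
    # Aalen-Johansen for competing risks: CIF_k(t) = sum_{s<=t} S(s-) d_k(s)/n(s)
    order = np.argsort(times, kind="mergesort")
    t_s, e_s = times[order], event_code[order]
    n_at_risk = times.size - np.searchsorted(t_s, grid, side="left")
    surv_prev = 1.0
    s_minus = np.empty(grid.size)
    d_any = np.zeros(grid.size)
    d_by = {k: np.zeros(grid.size) for k in range(1, len(cause_col_values) + 1)}
    idx = np.searchsorted(t_s, grid, side="left")
    idx_hi = np.searchsorted(t_s, grid, side="right")
    for i, (lo, hi_) in enumerate(zip(idx, idx_hi)):
        ev_here = e_s[lo:hi_]
        d_any[i] = np.sum(ev_here > 0)
        for k in d_by:
            d_by[k][i] = np.sum(ev_here == k)
        s_minus[i] = surv_prev
        if n_at_risk[i] > 0:
            surv_prev *= 1.0 - d_any[i] / n_at_risk[i]
    for k, c in enumerate(cause_col_values, start=1):
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(n_at_risk > 0, s_minus * d_by[k] / n_at_risk, 0.0)
        out[c] = pd.DataFrame({"time": grid, "cif": np.cumsum(inc)})
    return out


def _finegray_expand(
    dataset: pd.DataFrame,
    cause_of_interest: str,
    time_col: str,
    cause_col: str,
) -> pd.DataFrame:
    """Geskus-style IPCW risk-set expansion for the Fine-Gray model.

    Subjects failing from a competing cause remain at risk after their
    failure with time-varying weight G(t-)/G(T-), where G is the
    Kaplan-Meier estimate of the censoring distribution. The expanded data
    are counting-process rows (start, stop] with an ``ipcw`` weight column.

    The weight is a step function that changes only where G jumps (at
    observed censoring times), so extended risk is split at those times
    rather than at every event time of interest; the partial likelihood
    evaluated at event times is identical and the expansion stays compact
    under administrative censoring.
    """
    t = dataset[time_col].to_numpy(float)
    cause = dataset[cause_col].to_numpy()
    is_cens = cause == "censored"
    # censoring-distribution KM, G(t)
    kmf = KaplanMeierFitter()
    kmf.fit(t, is_cens.astype(int))
    g_grid = kmf.survival_function_.index.to_numpy(float)
    g_vals = kmf.survival_function_["KM_estimate"].to_numpy(float)

    def g_right(x: float) -> float:
        """Right-continuous G(t)."""
        idx = np.searchsorted(g_grid, x, side="right") - 1
        return 1.0 if idx < 0 else float(g_vals[idx])

    def g_minus(x: float) -> float:
        """Left-continuous G(t-)."""
        idx = np.searchsorted(g_grid, x, side="left") - 1
        return 1.0 if idx < 0 else float(g_vals[idx])

    interest_times = np.unique(t[cause == cause_of_interest])
    t_max = float(interest_times.max())
    cens_jumps = np.unique(t[is_cens])
    rows_start, rows_stop, rows_ev, rows_w, rows_idx = [], [], [], [], []
    competing = ~is_cens & (cause != cause_of_interest)
    for i in range(len(dataset)):
        ti = t[i]
        rows_start.append(0.0)
        rows_stop.append(ti)
        rows_ev.append(1 if cause[i] == cause_of_interest else 0)
        rows_w.append(1.0)
        rows_idx.append(i)
        if competing[i] and ti < t_max:
            jumps = cens_jumps[(cens_jumps > ti) & (cens_jumps < t_max)]
            cuts = np.concatenate([[ti], jumps, [t_max]])
            g_ti = g_minus(ti)
            for a, b in zip(cuts[:-1], cuts[1:]):
                # any event time in (a, b] sees weight G(a)/G(T-)
                rows_start.append(float(a))
                rows_stop.append(float(b))
                rows_ev.append(0)
                rows_w.append(g_right(float(a)) / g_ti)
                rows_idx.append(i)
    return pd.DataFrame(
        {
            "start": rows_start,
            "stop": rows_stop,
            "fg_event": rows_ev,
            "ipcw": rows_w,
            "_row": rows_idx,
        }
    )


def fit_subdistribution(
    dataset: pd.DataFrame,
    cause_of_interest: str = "hcc_death",
    covariates: list[str] | None = None,
    specification: str = "custom",
    time_col: str = "time_months",
    cause_col: str = "cause",
    ci_level: float = 0.95,
) -> ModelResult:
    """Fine-Gray subdistribution-hazard regression for one cause.

    Competing-event subjects are kept at risk with IPCW weights from the
    censoring-distribution Kaplan-Meier (risk-set expansion), and the
    weighted counting-process partial likelihood is maximized with a Cox
    solver (robust sandwich variance). With no competing events present the
    fit reduces to the cause-specific Cox model.
    """
    if cause_of_interest not in CAUSES[:2]:
        raise ValueError(f"cause_of_interest must be one of {CAUSES[:2]}")
    if (dataset[cause_col] == cause_of_interest).sum() == 0:
        raise ValueError(f"no events of cause {cause_of_interest!r}")
    df = dataset.reset_index(drop=True).copy()
    covariates = list(covariates) if covariates else []
    if specification == "group_model":
        covariates = ["group"] + [c for c in covariates if c != "group"]
    elif specification == "ptc_model":
        df["ptc_us_per10"] = df["ptc_us"] * 10.0
        df["ptc_ctmri_per10"] = df["ptc_ctmri"] * 10.0
        covariates = ["ptc_us_per10", "ptc_ctmri_per10"] + [
            c for c in covariates if not c.startswith("ptc")
        ]
    X, dropped = _design_matrix(df, covariates)
    expanded = _finegray_expand(df, cause_of_interest, time_col, cause_col)
    fit_df = pd.concat(
        [
            expanded[["start", "stop", "fg_event", "ipcw", "_row"]].reset_index(
                drop=True
            ),
            X.iloc[expanded["_row"].to_numpy()].reset_index(drop=True),
        ],
        axis=1,
    )
    fit_df = fit_df[fit_df["stop"] > fit_df["start"]]
    fit_df = fit_df[fit_df["ipcw"] > 0]
    cph = CoxPHFitter(alpha=1 - ci_level)
    try:
        cph.fit(
            fit_df,
            duration_col="stop",
            event_col="fg_event",
            entry_col="start",
            weights_col="ipcw",
            cluster_col="_row",
            robust=True,
        )
    except Exception as exc:
        raise ConvergenceError(f"Fine-Gray fit failed to converge: {exc}") from exc
    n_ev = int((df[cause_col] == cause_of_interest).sum())
    return _tidy_from_lifelines(
        cph, f"finegray:{cause_of_interest}:{specification}", len(df), n_ev, dropped
    )
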