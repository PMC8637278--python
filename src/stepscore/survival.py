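"""Survival analysis layer: Cox models, PH diagnostics, cut-points, KM, ABS.

Implements the statistical toolkit the STEP analysis runs on a cohort table:

* Kaplan-Meier product-limit estimation (direct numpy implementation — it is
  called ~1e5 times inside permutation loops);
* Cox proportional-hazards fits via lifelines, with optional time-dependent
  covariates ``x * f(t)`` realized by episode-splitting at event times;
* Schoenfeld-residual proportional-hazards diagnostics;
* stepwise variable selection alternating forward/backward steps with
  likelihood-ratio entry/stay tests (SLE = SLS = 0.15 by default);
* kernel-smoothed Youden-index cut-point selection;
* an area-between-survival-curves (ABS) permutation test for crossing
  Kaplan-Meier curves;
* hazard-ratio curves over virtual endpoints (administrative censoring at t)
  and landmarks (conditioning on survival past t);
* Mann-Whitney / chi-square two-group baseline comparisons.

Follow-up is death-censored: death with a functioning graft censors, it is
never an event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

FOLLOW_UP_CAP_YEARS = 10.0

#: covariates of the cohort table, in canonical order
COVARIATES = (
    "donor_age", "donor_sex", "recipient_age", "recipient_sex", "tx_year",
    "hpra", "repeat_tx", "donation_dbd", "cold_ischemia_h",
    "hla_mismatches", "eplet_mismatches", "ln_pirche", "step",
)

#: covariates treated as categorical in baseline comparisons
CATEGORICAL_COVARIATES = ("donor_sex", "recipient_sex", "repeat_tx", "donation_dbd")


class SurvivalError(Exception):
    """Estimation-layer error (degenerate input, non-convergence)."""


@dataclass(frozen=True)
class CohortRecord:
    """One transplant: baseline covariates plus death-censored follow-up.

    `repeat_tx` (reference: first transplant) and `donation_dbd`
    (reference: DCD) are 0/1 indicators; sexes are 0/1; `cold_ischemia_h`
    may be missing (None).  `time_years` is capped at 10; `event` is
    death-censored graft failure, `death` death with a functioning graft.
    """

    recipient_id: str
    donor_age: float
    donor_sex: int
    recipient_age: float
    recipient_sex: int
    tx_year: float
    hpra: float
    repeat_tx: int
    donation_dbd: int
    cold_ischemia_h: float | None
    hla_mismatches: float
    eplet_mismatches: float
    ln_pirche: float
    step: float
    time_years: float
    event: int
    death: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_years <= FOLLOW_UP_CAP_YEARS:
            raise ValueError(f"{self.recipient_id}: time_years outside [0, 10]")
        if self.event and self.death:
            raise ValueError(f"{self.recipient_id}: event and death both set")


def records_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = [{**{c: getattr(r, c) for c in COVARIATES},
             "recipient_id": r.recipient_id, "time_years": r.time_years,
             "event": r.event, "death": r.death} for r in records]
    return pd.DataFrame(rows)


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return records_to_frame(cohort)


# ---------------------------------------------------------------------------
# Kaplan-Meier

class KaplanMeier:
    """Right-continuous product-limit step function S(t), S(0) = 1."""

    def __init__(self, event_times: np.ndarray, survival: np.ndarray, tmax: float):
        self.event_times = event_times
        self.survival = survival
        self.tmax = tmax

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if self.event_times.size == 0:
            out = np.ones_like(t_arr)
        else:
            idx = np.searchsorted(self.event_times, t_arr, side="right")
            out = np.where(idx == 0, 1.0, self.survival[np.maximum(idx - 1, 0)])
        return float(out) if np.isscalar(t) else out

    def cumulative_incidence(self, t):
        return 1.0 - self(t)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeier:
    """Kaplan-Meier estimator from follow-up times and event indicators.

    Ties between censorings and events at the same time follow the usual
    convention: events precede censorings, so both count as at-risk at that
    time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if t.size == 0:
        raise ValueError("empty sample")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first
    deaths = np.add.reduceat(e.astype(np.int64), first)
    has_event = deaths > 0
    surv = np.cumprod(1.0 - deaths[has_event] / at_risk[has_event])
    return KaplanMeier(uniq[has_event], surv, tmax=float(t[-1]))


# ---------------------------------------------------------------------------
# Cox models

@dataclass(frozen=True)
class VariableEffect:
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    """Per-variable hazard ratios with 95% CIs and p-values."""

    effects: dict[str, VariableEffect]
    log_likelihood: float
    n: int
    n_events: int
    time_transform: dict[str, Callable] | None = None
    _fitter: object = field(default=None, repr=False, compare=False)
    _data: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.effects)


def _complete_cases(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    cols = list(variables) + ["time_years", "event"]
    return df[cols].dropna().reset_index(drop=True)


def _split_time_varying(df: pd.DataFrame, variables, time_transform) -> pd.DataFrame:
    """Long-format episode split at event times with x*f(t) columns appended."""
    cuts = np.unique(df.loc[df["event"] == 1, "time_years"].to_numpy())
    rows = []
    for sid, rec in enumerate(df.itertuples(index=False)):
        stop_times = cuts[cuts < rec.time_years].tolist() + [rec.time_years]
        start = 0.0
        for stop in stop_times:
            row = {"subject": sid, "start": start, "stop": stop,
                   "event": int(rec.event and stop == rec.time_years)}
            for v in variables:
                row[v] = getattr(rec, v)
            for v, f in time_transform.items():
                row[f"{v}_tt"] = getattr(rec, v) * f(stop)
            rows.append(row)
            start = stop
    return pd.DataFrame(rows)


def cox_fit(
    cohort,
    variables: Sequence[str],
    time_transform: Mapping[str, Callable] | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling).

    `time_transform` maps a variable name to a function f(t); each mapped
    variable additionally enters the model as ``x * f(t)``, evaluated at the
    event times via episode splitting (R's ``tt()`` construction).  Records
    with missing values in the selected variables are dropped listwise.
    """
    df = _complete_cases(_as_frame(cohort), list(variables))
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise SurvivalError(f"need at least 2 events, got {n_events}")
    try:
        if time_transform:
            long_df = _split_time_varying(df, variables, dict(time_transform))
            ctv = CoxTimeVaryingFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctv.fit(long_df, id_col="subject", start_col="start",
                        stop_col="stop", event_col="event")
            summary, fitter, ll = ctv.summary, ctv, float(ctv.log_likelihood_)
        else:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time_years", event_col="event")
            summary, fitter, ll = cph.summary, cph, float(cph.log_likelihood_)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise SurvivalError(f"Cox fit failed: {exc}") from exc
    effects = {
        name: VariableEffect(
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        ) for name, row in summary.iterrows()}
    return CoxResult(effects=effects, log_likelihood=ll, n=len(df),
                     n_events=n_events,
                     time_transform=dict(time_transform) if time_transform else None,
                     _fitter=fitter, _data=df)


def ph_check_schoenfeld(
    fit: CoxResult, transform: str = "km", alpha: float = 0.05
) -> dict[str, float]:
    """Schoenfeld-residual test of the proportional-hazards assumption.

    Scaled Schoenfeld residuals are regressed on the transformed time axis
    (default: the Kaplan-Meier transform); returns a p-value per variable.
    Variables with p < `alpha` warrant a time-dependent covariate.
    """
    if not isinstance(fit._fitter, CoxPHFitter):
        raise SurvivalError("PH check requires a plain (non-time-varying) Cox fit")
    if fit.n_events < 2:
        raise SurvivalError("PH check needs at least 2 events")
    res = proportional_hazard_test(fit._fitter, fit._data, time_transform=transform)
    pvals = res.summary["p"]
    if isinstance(pvals.index, pd.MultiIndex):
        pvals = pvals.droplevel(-1)
    return {str(v): float(p) for v, p in pvals.items()}


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(stat, df))


def _partial_ll(df: pd.DataFrame, variables: Sequence[str]) -> float:
    """Partial log-likelihood; closed form (Efron, beta = 0) for the null model."""
    if not variables:
        t = df["time_years"].to_numpy(dtype=float)
        e = df["event"].to_numpy(dtype=bool)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq, first = np.unique(t, return_index=True)
        at_risk = t.size - first
        deaths = np.add.reduceat(e.astype(np.int64), first)
        ll = 0.0
        for n_j, d_j in zip(at_risk, deaths):
            ll -= sum(np.log(n_j - l) for l in range(d_j))
        return float(ll)
    return cox_fit(df, list(variables)).log_likelihood


def stepwise_select(
    cohort,
    candidates: Sequence[str],
    sle: float = 0.15,
    sls: float = 0.15,
    max_steps: int = 50,
) -> CoxResult:
    """Stepwise Cox model selection alternating forward and backward moves.

    Forward: add the candidate with the smallest likelihood-ratio p-value if
    p < `sle` (ties broken by candidate order).  Backward: drop the retained
    variable with the largest LR p-value if p > `sls`.  Iterate until stable.
    All candidate columns are reduced to complete cases once, up front, so
    every nested test compares models on identical rows.  May return an
    empty model.
    """
    if not candidates:
        df0 = _complete_cases(_as_frame(cohort), [])
        return CoxResult(effects={}, log_likelihood=float("nan"),
                         n=len(df0), n_events=int(df0["event"].sum()))
    df = _complete_cases(_as_frame(cohort), list(candidates))
    selected: list[str] = []
    ll_cache: dict[tuple[str, ...], float] = {}

    def ll(model: Sequence[str]) -> float:
        key = tuple(sorted(model))
        if key not in ll_cache:
            ll_cache[key] = _partial_ll(df, list(key))
        return ll_cache[key]

    seen_states: set[tuple[str, ...]] = set()
    for _ in range(max_steps):
        state = tuple(sorted(selected))
        if state in seen_states:  # oscillation guard
            break
        seen_states.add(state)
        changed = False
        # forward: best LR entry p-value below SLE
        entries = [(c, _lr_pvalue(ll(selected + [c]), ll(selected), 1))
                   for c in candidates if c not in selected]
        entries = [(c, p) for c, p in entries if p < sle]
        if entries:
            best, _ = min(entries, key=lambda cp: cp[1])
            selected.append(best)
            changed = True
        # backward: worst LR stay p-value above SLS
        if selected:
            exits = [(v, _lr_pvalue(ll(selected), ll([u for u in selected if u != v]), 1))
                     for v in selected]
            worst, worst_p = max(exits, key=lambda vp: vp[1])
            if worst_p > sls:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    if not selected:
        return CoxResult(effects={}, log_likelihood=ll([]),
                         n=len(df), n_events=int(df["event"].sum()))
    return cox_fit(df, selected)


# ---------------------------------------------------------------------------
# cut-point selection

@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    youden_j: float


def youden_cutpoint_kernel(
    scores: Sequence[float], labels: Sequence[bool], grid_size: int = 512
) -> CutpointResult:
    """Optimal cutoff maximizing the Youden index on kernel-smoothed CDFs.

    Gaussian kernels with Silverman's bandwidth smooth the score CDFs of the
    non-event (F0) and event (F1) groups; the cutoff maximizes
    J(c) = F0(c) - F1(c) = sensitivity + specificity - 1 under the
    higher-score -> event convention.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    x0, x1 = s[~y], s[y]
    if x0.size == 0 or x1.size == 0:
        raise SurvivalError("both classes are required for cut-point selection")

    def bandwidth(x: np.ndarray) -> float:
        sd = np.std(x, ddof=1) if x.size > 1 else 0.0
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return max(0.9 * spread * x.size ** (-0.2), 1e-9)

    h0, h1 = bandwidth(x0), bandwidth(x1)
    lo = min(x0.min() - 3 * h0, x1.min() - 3 * h1)
    hi = max(x0.max() + 3 * h0, x1.max() + 3 * h1)
    grid = np.linspace(lo, hi, grid_size)
    f0 = stats.norm.cdf((grid[:, None] - x0[None, :]) / h0).mean(axis=1)
    f1 = stats.norm.cdf((grid[:, None] - x1[None, :]) / h1).mean(axis=1)
    j = f0 - f1
    best = int(np.argmax(j))
    return CutpointResult(cutoff=float(grid[best]), youden_j=float(j[best]))


# ---------------------------------------------------------------------------
# ABS permutation test

@dataclass(frozen=True)
class AbsTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _abs_statistic(times: np.ndarray, events: np.ndarray, mask: np.ndarray) -> float:
    """Integrated |S1(t) - S2(t)| up to the smaller of the groups' last times."""
    km1 = km_estimate(times[mask], events[mask])
    km2 = km_estimate(times[~mask], events[~mask])
    tau = min(km1.tmax, km2.tmax)
    grid = np.unique(np.concatenate(
        ([0.0], km1.event_times, km2.event_times, [tau])))
    grid = grid[grid <= tau]
    if grid.size < 2:
        return 0.0
    diffs = np.abs(km1(grid[:-1]) - km2(grid[:-1]))
    return float(np.sum(diffs * np.diff(grid)))


def abs_permutation_test(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> AbsTestResult:
    """Area-between-survival-curves permutation test for two groups.

    The statistic integrates |S1 - S2| over the merged event-time grid up to
    the smaller of the two groups' last observed times; the null distribution
    permutes group labels.  p uses the add-one rule
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise SurvivalError(f"expected exactly 2 groups, got {levels.size}")
    mask = g == levels[0]
    if not (e[mask].any() and e[~mask].any()):
        raise SurvivalError("each group needs at least one event")
    observed = _abs_statistic(t, e, mask)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _abs_statistic(t, e, rng.permutation(mask)) >= observed
    return AbsTestResult(statistic=observed,
                         p_value=(1 + hits) / (1 + n_perm),
                         n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# HR curves (Fig.-5-style diagnostics)

@dataclass(frozen=True)
class HrCurvePoint:
    t: float
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    n_events: int
    skipped: str | None = None


def _fit_point(df: pd.DataFrame, variable: str, covariates: Sequence[str],
               t: float, min_events: int) -> HrCurvePoint:
    n_events = int(df["event"].sum())
    if n_events < min_events:
        return HrCurvePoint(t=t, hr=None, ci_low=None, ci_high=None,
                            n_events=n_events,
                            skipped=f"{n_events} events < minimum {min_events}")
    fit = cox_fit(df, list(covariates))
    eff = fit.effects[variable]
    return HrCurvePoint(t=t, hr=eff.hr, ci_low=eff.ci_low, ci_high=eff.ci_high,
                        n_events=n_events)


def hr_virtual_endpoints(
    cohort, variable: str, grid: Sequence[float],
    covariates: Sequence[str] | None = None, min_events: int = 5,
) -> list[HrCurvePoint]:
    """HR of `variable` when follow-up is administratively cut at each t.

    At each grid time every record is censored at t (events after t become
    censorings); grid points with fewer than `min_events` events are skipped
    with a reason.  At t >= the follow-up cap this reproduces the full fit.
    """
    covariates = list(covariates) if covariates else [variable]
    base = _complete_cases(_as_frame(cohort), covariates)
    out = []
    for t in grid:
        df = base.copy()
        df["event"] = np.where(df["time_years"] <= t, df["event"], 0)
        df["time_years"] = np.minimum(df["time_years"], t)
        out.append(_fit_point(df, variable, covariates, float(t), min_events))
    return out


def hr_landmark(
    cohort, variable: str, grid: Sequence[float],
    covariates: Sequence[str] | None = None, min_events: int = 5,
) -> list[HrCurvePoint]:
    """HR of `variable` among subjects still event-free past each landmark t.

    Records with follow-up <= t are excluded; the remaining records keep the
    original time origin (survival to t is conditioned on, not re-timed).
    At t = 0 this reproduces the full fit.
    """
    covariates = list(covariates) if covariates else [variable]
    base = _complete_cases(_as_frame(cohort), covariates)
    out = []
    for t in grid:
        df = base[base["time_years"] > t].reset_index(drop=True)
        out.append(_fit_point(df, variable, covariates, float(t), min_events))
    return out


# ---------------------------------------------------------------------------
# two-group baseline comparison

def group_compare(
    cohort,
    group: Sequence[bool],
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
) -> dict[str, float]:
    """Baseline comparison of two groups: Mann-Whitney U / Pearson chi-square.

    Continuous variables use the exact-tie-corrected two-sided Mann-Whitney U
    test; categorical variables the Pearson chi-square test without
    continuity correction.  Missing values are dropped per variable.
    """
    df = _as_frame(cohort)
    g = np.asarray(group, dtype=bool)
    if g.all() or not g.any():
        raise SurvivalError("both groups must be non-empty")
    if continuous is None:
        continuous = [c for c in COVARIATES if c not in CATEGORICAL_COVARIATES]
    if categorical is None:
        categorical = list(CATEGORICAL_COVARIATES)
    out: dict[str, float] = {}
    for var in continuous:
        x = df[var].to_numpy(dtype=float)
        keep = ~np.isnan(x)
        a, b = x[keep & g], x[keep & ~g]
        if np.array_equal(np.sort(a), np.sort(b)):
            out[var] = 1.0
        else:
            out[var] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    for var in categorical:
        tab = pd.crosstab(df[var], pd.Series(g, index=df.index))
        if tab.shape[0] < 2:
            out[var] = 1.0
        else:
            out[var] = float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])
    return out
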