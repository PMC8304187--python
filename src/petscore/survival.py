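"""Survival statistics: Spearman correlation, maximally selected chi-square
cutpoints, Cox proportional-hazards models, Harrell's C-index and
Kaplan-Meier summaries.

The maximally selected chi-square test and Harrell's concordance index are
implemented here with explicitly stated conventions (see the individual
functions); ordinary Cox fitting and the product-limit estimator delegate to
lifelines, and Spearman correlation to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

__all__ = [
    "CutoffResult",
    "CoxModelResult",
    "KMCurve",
    "spearman_correlation",
    "logrank_chi2",
    "maxstat_cutoff",
    "cox_fit",
    "harrell_c",
    "km_estimate",
]


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _logrank_terms(group_matrix: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log-rank score U and variance V for each column of a 0/1 group matrix.

    Vectorized over candidate groupings: column k of ``group_matrix`` assigns
    each subject to group 1 (True) or 0. Returns (U, V) with
    U = sum over event times of (observed - expected deaths in group 1) and V
    the hypergeometric variance, so chi-square = U^2 / V.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = group_matrix[order].astype(np.float64)

    # suffix cumulative group membership -> group-1 at-risk counts
    suffix = np.cumsum(g[::-1], axis=0)[::-1]
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    n_at = n - start  # total at risk at each distinct time
    n1_at = suffix[start]  # (n_times, K)
    d = np.add.reduceat(e, start)  # deaths at each distinct time
    d1 = np.add.reduceat(e[:, None] * g, start, axis=0)

    has_event = d > 0
    d = d[has_event]
    n_at = n_at[has_event].astype(np.float64)
    n1_at = n1_at[has_event]
    d1 = d1[has_event]

    frac = n1_at / n_at[:, None]
    U = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = (
            d[:, None]
            * frac
            * (1.0 - frac)
            * ((n_at - d) / np.maximum(n_at - 1.0, 1.0))[:, None]
        )
    V = var_terms.sum(axis=0)
    return U, V


def logrank_chi2(group, time, event) -> float:
    """Two-group log-rank chi-square statistic (1 degree of freedom)."""
    group = np.asarray(group).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    U, V = _logrank_terms(group[:, None], time, event)
    if V[0] <= 0:
        raise ValueError("log-rank variance is zero (degenerate grouping)")
    return float(U[0] ** 2 / V[0])


@dataclass(frozen=True)
class CutoffResult:
    """Optimal dichotomization cutpoint of one continuous variable.

    ``p_value`` is the naive chi-square(1) tail of the maximal statistic;
    ``p_value_corrected`` applies the Lausen-Schumacher selection correction
    and is the honest p-value of the search.
    """

    variable: str
    cutoff: float
    chi2: float
    p_value: float
    p_value_corrected: float
    direction: str  # "high" if values above the cutoff carry excess hazard
    n_candidates: int
    candidate_range: tuple[float, float]


def _lausen_schumacher_p(chi2: float, eps_low: float, eps_high: float) -> float:
    """Improved Bonferroni-type p-value for a maximally selected statistic."""
    b = math.sqrt(max(chi2, 1e-12))
    if b < 1e-6:
        return 1.0
    log_odds = math.log((1.0 - eps_low) * eps_high / (eps_low * (1.0 - eps_high)))
    p = stats.norm.pdf(b) * ((b - 1.0 / b) * log_odds + 4.0 / b)
    return float(min(max(p, 0.0), 1.0))


def maxstat_cutoff(
    values,
    time,
    event,
    variable: str = "x",
    quantile_bounds: tuple[float, float] = (0.10, 0.90),
    min_group: int = 3,
) -> CutoffResult:
    """Maximally selected chi-square dichotomization of a continuous variable.

    Every observed value between the quantile bounds is a candidate cutpoint
    c; subjects are split as "<= c" vs "> c", the two-group log-rank
    chi-square is computed for each split, and the c with the maximal
    statistic is returned (ties broken toward the smaller cutoff).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = values.size
    if not (time.size == n == event.size):
        raise ValueError("values, time and event must have equal length")
    if n < 20:
        raise ValueError(f"need at least 20 subjects for cutpoint selection, got {n}")
    if event.sum() < 5:
        raise ValueError(f"need at least 5 events, got {int(event.sum())}")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; no cutpoint exists")
    lo_q, hi_q = quantile_bounds
    if not 0.0 <= lo_q < hi_q <= 1.0:
        raise ValueError(f"invalid quantile bounds {quantile_bounds}")

    lo, hi = np.quantile(values, [lo_q, hi_q])
    candidates = np.unique(values)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    # a cutoff at the maximum would leave the ">" group empty
    candidates = candidates[candidates < values.max()]
    n_above = (values[:, None] > candidates[None, :]).sum(axis=0)
    ok = (n_above >= min_group) & (n - n_above >= min_group)
    candidates = candidates[ok]
    if candidates.size == 0:
        raise ValueError(
            f"no candidate cutoff leaves at least {min_group} subjects per group"
        )

    group = values[:, None] > candidates[None, :]
    U, V = _logrank_terms(group, time, event)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U**2 / V, 0.0)
    best = int(np.argmax(chi2))  # argmax takes the first (smallest) cutoff on ties
    eps_low = float((values <= candidates[0]).mean())
    eps_high = float((values <= candidates[-1]).mean())
    return CutoffResult(
        variable=variable,
        cutoff=float(candidates[best]),
        chi2=float(chi2[best]),
        p_value=float(stats.chi2.sf(chi2[best], df=1)),
        p_value_corrected=_lausen_schumacher_p(float(chi2[best]), eps_low, eps_high),
        direction="high" if U[best] > 0 else "low",
        n_candidates=int(candidates.size),
        candidate_range=(float(candidates[0]), float(candidates[-1])),
    )


@dataclass(frozen=True)
class CoxModelResult:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per model term with columns hazard_ratio,
    ci_lower, ci_upper, p_value and coef.
    """

    label: str
    summary: pd.DataFrame
    c_index: float
    c_index_ci: tuple[float, float] | None
    n: int
    n_events: int
    warnings: tuple[str, ...] = ()

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hazard_ratio"])


def _design_matrix(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design columns; object/categorical columns are dummy-coded."""
    parts = []
    for col in columns:
        if col not in cohort.columns:
            raise KeyError(f"cohort has no column '{col}'")
        series = cohort[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(series.astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    adjust: list[str] | None = None,
    time_col: str = "time_months",
    event_col: str = "event",
    label: str | None = None,
) -> CoxModelResult:
    """Fit a Cox model (Efron tie handling) for covariates plus adjusters.

    A univariable analysis in the study's sense is one covariate with
    ``adjust=["age", "sex"]``; a multivariable model lists all covariates.
    Events fewer than 10 per free covariate trigger a warning (the usual rule
    of thumb), not a failure.
    """
    adjust = list(adjust or [])
    design = _design_matrix(cohort, list(covariates) + adjust)
    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"missing values in model columns {bad}")
    df = design.copy()
    df[time_col] = np.asarray(cohort[time_col], dtype=float)
    df[event_col] = np.asarray(cohort[event_col], dtype=int)

    n_events = int(df[event_col].sum())
    warnings: list[str] = []
    k = design.shape[1]
    if n_events < 10 * k:
        warnings.append(
            f"{n_events} events for {k} model terms; below the 10-events-per-"
            "covariate rule of thumb"
        )

    cph = CoxPHFitter()
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=time_col, event_col=event_col)
        except Exception as exc:  # lifelines raises ConvergenceError/ValueError
            raise RuntimeError(
                f"Cox model did not converge (possible complete separation): {exc}"
            ) from exc
    warnings.extend(str(w.message).split("\n")[0] for w in caught)
    if not np.all(np.isfinite(cph.params_)) or np.any(np.abs(cph.params_) > 20):
        raise RuntimeError(
            "Cox model coefficients diverged (complete separation in a covariate)"
        )

    with np.errstate(over="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        summary = pd.DataFrame(
            {
                "coef": cph.params_,
                "hazard_ratio": np.exp(cph.params_),
                "ci_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
                "ci_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
                "p_value": cph.summary["p"],
            }
        )
    risk = design.values @ cph.params_.values
    c_index, _ = harrell_c(risk, df[time_col].values, df[event_col].values)
    return CoxModelResult(
        label=label or " + ".join(covariates),
        summary=summary,
        c_index=c_index,
        c_index_ci=None,
        n=int(len(df)),
        n_events=n_events,
        warnings=tuple(warnings),
    )


def _concordance(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """(concordant-weighted count, usable-pair count) under Harrell's rules.

    A pair is usable when the subject with the shorter time has an event, or
    when times tie and exactly one subject has an event (the censored one is
    the longer survivor). Risk ties count 0.5.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None].astype(bool)
    e_j = event[None, :].astype(bool)
    usable = (t_i < t_j) & e_i | ((t_i == t_j) & e_i & ~e_j)
    r_i = risk[:, None]
    r_j = risk[None, :]
    conc = np.where(r_i > r_j, 1.0, np.where(r_i == r_j, 0.5, 0.0))
    return float((conc * usable).sum()), float(usable.sum())


def harrell_c(
    risk,
    time,
    event,
    n_boot: int = 0,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float] | None]:
    """Harrell's concordance index with an optional bootstrap CI.

    Returns (C, (lo, hi)) — the CI is None unless ``n_boot > 0``, in which
    case it is a seeded percentile bootstrap over patients.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (risk.size == time.size == event.size):
        raise ValueError("risk, time and event must have equal length")
    num, den = _concordance(risk, time, event)
    if den == 0:
        raise ValueError("no usable pairs; concordance is undefined")
    c = num / den
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = risk.size
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            bn, bd = _concordance(risk[idx], time[idx], event[idx])
            if bd > 0:
                reps.append(bn / bd)
        ci = (
            float(np.quantile(reps, alpha / 2)),
            float(np.quantile(reps, 1 - alpha / 2)),
        )
    return float(c), ci


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier survival curve with median and horizon summaries.

    ``median`` is NaN when the curve never reaches 0.5 (median undefined);
    ``horizon_extrapolated`` flags a queried horizon beyond the last observed
    time, where the step function is carried forward.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]
    horizon: float | None
    horizon_survival: float | None
    horizon_extrapolated: bool
    n: int
    n_events: int


def km_estimate(time, event, horizon: float | None = None) -> KMCurve:
    """Product-limit estimate of the survivor function.

    The median is the earliest time with S(t) <= 0.5; its confidence interval
    follows the Brookmeyer-Crowley construction (times at which the pointwise
    survival CI brackets 0.5). Unreachable bounds are +inf.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = float("nan")  # survival never drops to 0.5
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])

    horizon_survival = None
    extrapolated = False
    if horizon is not None:
        if horizon > time.max():
            extrapolated = True
        horizon_survival = float(
            kmf.predict(min(horizon, float(times.max())))
        )
    return KMCurve(
        times=times,
        survival=surv,
        median=median,
        median_ci=(lo, hi),
        horizon=horizon,
        horizon_survival=horizon_survival,
        horizon_extrapolated=extrapolated,
        n=int(time.size),
        n_events=int(event.sum()),
    )
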