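"""Survival estimators and the mortality analysis.

Nonparametric Kaplan-Meier and Nelson-Aalen estimators, the Mantel-Cox
log-rank test, lifespan summaries, the mid-life Gompertz fit, the late-life
mortality-plateau estimate, and the temporal-scaling collapse of survival
curves.  The two-regime analysis — exponential (Gompertz) mortality near the
mean lifespan, a hazard plateau late in life — is the demographic face of the
critical-mode model in :mod:`critaging.core_model`.

Conventions: at tied times deaths precede censorings (censored animals count
as at risk); mean lifespan averages uncensored deaths only (lost animals are
excluded); the cumulative-hazard variance is the Poisson form sum(d/n^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .events import validate_event_table
from .core_model import GompertzLaw, gompertz_cumhaz

__all__ = [
    "SurvivalCurve",
    "CumulativeHazard",
    "GompertzFit",
    "PlateauEstimate",
    "LifespanSummary",
    "kaplan_meier",
    "nelson_aalen",
    "logrank_test",
    "lifespan_summary",
    "relative_extension",
    "fit_gompertz",
    "fit_gompertz_curve",
    "estimate_plateau",
    "rescale_and_collapse",
    "plateau_vs_alpha_report",
]


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray          # distinct event (death) times, increasing
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk at each event time
    group: str = "cohort"


@dataclass(frozen=True)
class CumulativeHazard:
    times: np.ndarray
    values: np.ndarray         # m(t) = sum d_i/n_i
    variance: np.ndarray       # sum d_i/n_i^2
    group: str = "cohort"


@dataclass(frozen=True)
class GompertzFit:
    M0: float
    alpha: float
    window: tuple[float, float]    # time window actually used (days)
    residual_norm: float


@dataclass(frozen=True)
class PlateauEstimate:
    M_plateau: float
    se: float
    window: tuple[float, float]    # tail time window (days)
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LifespanSummary:
    mean_lifespan: float           # mean over uncensored deaths
    max_lifespan: float            # last observed death
    n: int
    n_censored: int
    km_restricted_mean: float      # integral of the KM curve to the last event


def _death_counts(events: pd.DataFrame):
    """Distinct death times with death counts and numbers at risk."""
    validate_event_table(events)
    t = events["time_days"].to_numpy(float)
    e = events["event"].to_numpy(int)
    death_times = np.unique(t[e == 1])
    d = np.array([np.sum((t == ti) & (e == 1)) for ti in death_times])
    # deaths precede censorings at ties: anyone with time >= ti is at risk
    n = np.array([np.sum(t >= ti) for ti in death_times])
    return death_times, d, n


def kaplan_meier(events: pd.DataFrame) -> SurvivalCurve:
    """Product-limit survival estimate under right-censoring."""
    times, d, n = _death_counts(events)
    group = str(events["group"].iloc[0])
    surv = np.cumprod(1.0 - d / n)
    return SurvivalCurve(times=times, survival=surv, at_risk=n, group=group)


def nelson_aalen(events: pd.DataFrame) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard m(t) = sum d_i/n_i with variance sum d_i/n_i^2."""
    times, d, n = _death_counts(events)
    group = str(events["group"].iloc[0])
    return CumulativeHazard(
        times=times,
        values=np.cumsum(d / n),
        variance=np.cumsum(d / n**2),
        group=group,
    )


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Cox log-rank test (1 df) between two cohorts.

    Returns (chi-square statistic, p-value).
    """
    validate_event_table(a)
    validate_event_table(b)
    if (a["event"] == 1).sum() + (b["event"] == 1).sum() == 0:
        # identical all-censored tables carry no information
        return 0.0, 1.0
    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(
        a["time_days"], b["time_days"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def lifespan_summary(events: pd.DataFrame) -> LifespanSummary:
    """Mean/max adult lifespan over observed deaths, plus the KM restricted mean."""
    validate_event_table(events)
    e = events["event"].to_numpy(int)
    if (e == 1).sum() == 0:
        raise ValueError("no deaths observed; lifespan summary undefined")
    deaths = events.loc[events["event"] == 1, "time_days"].to_numpy(float)
    curve = kaplan_meier(events)
    # integral of the step function S(t) from 0 to the last death time
    t_edges = np.concatenate([[0.0], curve.times])
    s_left = np.concatenate([[1.0], curve.survival[:-1]])
    rmean = float(np.sum(s_left * np.diff(t_edges)))
    return LifespanSummary(
        mean_lifespan=float(deaths.mean()),
        max_lifespan=float(deaths.max()),
        n=int(len(events)),
        n_censored=int((e == 0).sum()),
        km_restricted_mean=rmean,
    )


def relative_extension(
    treated: float, control: float, rounding: str = "one-decimal"
) -> float:
    """Relative lifespan extension in percent, 100*(treated-control)/control.

    ``rounding``: 'one-decimal' (printed convention below 100%), 'nearest-ten'
    (convention for very large extensions), or 'none'.
    """
    if control <= 0:
        raise ValueError("control lifespan must be > 0")
    pct = 100.0 * (treated - control) / control
    if rounding == "one-decimal":
        return round(pct, 1)
    if rounding == "nearest-ten":
        return round(pct / 10.0) * 10.0
    if rounding == "none":
        return pct
    raise ValueError(f"unknown rounding {rounding!r}")


def fit_gompertz_curve(times: np.ndarray, cumhaz: np.ndarray) -> GompertzFit:
    """Least-squares Gompertz fit of a cumulative-hazard curve.

    Fits m(t) = (M0/alpha)(exp(alpha t) - 1) in log-parameters (both rates
    positive).  Used by :func:`fit_gompertz` after windowing; exposed
    separately so exact closed-form curves can be fitted directly.
    """
    times = np.asarray(times, float)
    cumhaz = np.asarray(cumhaz, float)
    if len(times) < 3:
        raise ValueError("need at least 3 points to fit")

    def model(t, log_m0, log_a):
        m0, a = np.exp(log_m0), np.exp(log_a)
        return m0 / a * np.expm1(a * t)

    t_span = times.max() - times.min() if times.max() > times.min() else times.max()
    # crude initialization from the endpoints of the window
    a0 = max(np.log(max(cumhaz[-1] / max(cumhaz[0], 1e-12), 1.001)) / max(t_span, 1e-12), 1e-4)
    m00 = max(cumhaz[-1] / max(np.expm1(a0 * times[-1]) / a0, 1e-12), 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            model, times, cumhaz, p0=[np.log(m00), np.log(a0)], maxfev=20000
        )
    except RuntimeError as err:
        resid = float(np.linalg.norm(cumhaz - model(times, np.log(m00), np.log(a0))))
        raise RuntimeError(
            f"Gompertz fit did not converge (initial residual norm {resid:.3g})"
        ) from err
    M0, alpha = float(np.exp(popt[0])), float(np.exp(popt[1]))
    resid = float(np.linalg.norm(cumhaz - model(times, *popt)))
    return GompertzFit(
        M0=M0, alpha=alpha, window=(float(times.min()), float(times.max())),
        residual_norm=resid,
    )


def fit_gompertz(
    events: pd.DataFrame,
    window: tuple[float, float] = (0.9, 0.25),
    min_deaths: int = 10,
) -> GompertzFit:
    """Gompertz fit of the Nelson-Aalen cumulative hazard near the mean lifespan.

    Only event times where the Kaplan-Meier survival lies inside the
    survival-quantile ``window`` (default [0.9, 0.25], bracketing the mean
    lifespan) enter the fit, since the network stiffness coincides with the
    Gompertz exponent only in that neighbourhood.
    """
    hi, lo = max(window), min(window)
    curve = kaplan_meier(events)
    haz = nelson_aalen(events)
    mask = (curve.survival <= hi) & (curve.survival >= lo)
    n_deaths = int(
        events.loc[
            (events["event"] == 1)
            & events["time_days"].isin(curve.times[mask]),
            "event",
        ].sum()
    )
    if n_deaths < min_deaths:
        raise ValueError(
            f"only {n_deaths} deaths inside survival window {window}; need >= {min_deaths}"
        )
    return fit_gompertz_curve(haz.times[mask], haz.values[mask])


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def estimate_plateau(
    events: pd.DataFrame,
    tail: float = 0.2,
    midlife_window: tuple[float, float] = (0.65, 0.35),
) -> PlateauEstimate:
    """Late-life plateau mortality from the cumulative-hazard tail.

    Ordinary least squares of m(t) on t over the event times after the last
    ``tail`` fraction of deaths has begun (default: after 80% of deaths).
    Where the hazard has plateaued, m(t) is linear and the slope estimates
    M(t >> tbar).  Diagnostics compare the slope against the mid-life hazard
    (the same regression over the central survival window): for strictly
    Gompertz data the tail slope far exceeds the mid-life hazard and the
    ``exceeds_midlife`` flag is set.
    """
    if not (0 < tail < 1):
        raise ValueError("tail must be in (0, 1)")
    haz = nelson_aalen(events)
    deaths = np.sort(events.loc[events["event"] == 1, "time_days"].to_numpy(float))
    if len(deaths) == 0:
        raise ValueError("no deaths; plateau undefined")
    t_tail = deaths[int(np.floor((1.0 - tail) * len(deaths)))]
    mask = haz.times >= t_tail
    if mask.sum() < 3:
        raise ValueError(
            f"tail window contains {int(mask.sum())} distinct event times; need >= 3"
        )
    slope, se = _ols_slope(haz.times[mask], haz.values[mask])
    diagnostics: dict = {}
    curve = kaplan_meier(events)
    mid = (curve.survival <= midlife_window[0]) & (curve.survival >= midlife_window[1])
    if mid.sum() >= 3:
        mid_slope, _ = _ols_slope(haz.times[mid], haz.values[mid])
        ratio = slope / mid_slope if mid_slope > 0 else np.inf
        diagnostics = {
            "midlife_hazard": mid_slope,
            "plateau_to_midlife": ratio,
            "exceeds_midlife": bool(ratio > 2.0 and slope - mid_slope > 2 * se),
        }
    return PlateauEstimate(
        M_plateau=float(slope), se=float(se),
        window=(float(t_tail), float(haz.times.max())),
        diagnostics=diagnostics,
    )


def rescale_and_collapse(
    curves: list[SurvivalCurve],
    lifespans: list[float],
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Temporal-scaling collapse of survival curves.

    Each curve is re-expressed as a step function of age rescaled by its
    cohort mean lifespan on a common grid t/tbar in [0, 2]; the collapse
    statistic is the maximum over curve pairs of the sup-distance between
    rescaled curves (0 = perfect collapse).  Returns the statistic and a
    table of the rescaled curves (one column per group).
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    if len(curves) != len(lifespans):
        raise ValueError("need one lifespan per curve")
    if any(t <= 0 for t in lifespans):
        raise ValueError("lifespans must be > 0")
    if grid is None:
        grid = np.linspace(0.0, 2.0, 401)
    cols = {}
    for curve, tbar in zip(curves, lifespans):
        t_resc = np.concatenate([[0.0], curve.times / tbar])
        s = np.concatenate([[1.0], curve.survival])
        idx = np.clip(np.searchsorted(t_resc, grid, side="right") - 1, 0, len(s) - 1)
        cols[curve.group] = s[idx]
    table = pd.DataFrame(cols, index=pd.Index(grid, name="rescaled_age"))
    vals = table.to_numpy()
    stat = 0.0
    for i in range(vals.shape[1]):
        for j in range(i + 1, vals.shape[1]):
            stat = max(stat, float(np.max(np.abs(vals[:, i] - vals[:, j]))))
    return stat, table


def plateau_vs_alpha_report(
    cohorts: list[pd.DataFrame],
    window: tuple[float, float] = (0.9, 0.25),
    tail: float = 0.2,
) -> pd.DataFrame:
    """Per-cohort (Gompertz exponent, plateau mortality, mean lifespan) table.

    One row per cohort; rows where either estimator fails are flagged via the
    ``error`` column rather than aborting the report.  Intended for the
    plateau-versus-alpha scatter against the identity line.
    """
    rows = []
    for events in cohorts:
        group = str(events["group"].iloc[0])
        row = {
            "group": group, "alpha_hat": np.nan, "M0_hat": np.nan,
            "M_plateau": np.nan, "plateau_se": np.nan, "tbar": np.nan,
            "error": "",
        }
        try:
            summ = lifespan_summary(events)
            row["tbar"] = summ.mean_lifespan
            fit = fit_gompertz(events, window=window)
            row["alpha_hat"] = fit.alpha
            row["M0_hat"] = fit.M0
            plat = estimate_plateau(events, tail=tail)
            row["M_plateau"] = plat.M_plateau
            row["plateau_se"] = plat.se
        except (ValueError, RuntimeError) as err:
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)
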