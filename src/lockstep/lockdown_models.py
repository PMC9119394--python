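"""Per-participant regression models of activity on the interruption indicator.

Three model families, all with a log-scale outcome so the interruption
coefficient back-transforms to a relative rate (post/pre ratio):

* minute-level METs — log(minute MET) regressed on the indicator L, harmonic
  time-of-day terms sin(2πt/24) and cos(2πt/24), and their interactions with
  L, with AR(1) errors (generalised least squares, iterated Prais–Winsten
  estimation of the autocorrelation);
* daily steps — negative-binomial regression (log link) of the day total on L
  with a wear-habit adjustment;
* daily intensity minutes — log(minutes + 1) on L and wear minutes with AR(1)
  errors over the day sequence.

The harmonic terms absorb shifts in time-of-day wear habits so that L captures
the level change rather than a change in when the device was worn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activity_metrics import IntensityCategory
from .data_io import LockdownCalendar, ParticipantSeries

__all__ = [
    "FitError",
    "HarmonicCovariates",
    "ModelFit",
    "harmonic_covariates",
    "harmonic_design",
    "fit_mets_model",
    "fit_daily_steps_model",
    "fit_daily_intensity_model",
    "fit_participant",
    "fit_participant_daily",
    "fits_dataframe",
    "OUTCOME_COLUMNS",
]

#: Daily-summary column carrying each intensity outcome.
OUTCOME_COLUMNS = {
    IntensityCategory.SEDENTARY: "sedentary_min",
    IntensityCategory.LIGHTLY_ACTIVE: "light_min",
    IntensityCategory.FAIRLY_ACTIVE: "fair_min",
    IntensityCategory.VERY_ACTIVE: "very_min",
}

#: Default minimum observations per lockdown state before a fit is attempted.
MIN_DAYS_PER_STATE = 30
MIN_MINUTES_PER_STATE = 5_000

_AR_CONVERGENCE_RTOL = 1e-8
_AR_MAX_ITER = 50


class FitError(RuntimeError):
    """A model could not be fitted (too little data or non-convergence)."""


@dataclass(frozen=True)
class HarmonicCovariates:
    """First-harmonic time-of-day covariates of a minute timestamp."""

    t: float  # hours in [0, 24)
    s: float  # sin(2*pi*t/24)
    c: float  # cos(2*pi*t/24)


@dataclass(frozen=True)
class ModelFit:
    """One participant x outcome interruption coefficient on the log scale."""

    participant_id: str
    outcome: str
    beta_lockdown: float
    se: float
    n_obs: int
    rho: float | None = None  # fitted AR(1) coefficient, where applicable
    theta: float | None = None  # NB dispersion, steps model only

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise FitError(f"{self.participant_id}/{self.outcome}: non-positive SE")
        if self.rho is not None and not abs(self.rho) < 1:
            raise FitError(f"{self.participant_id}/{self.outcome}: |rho| >= 1")


def harmonic_covariates(timestamp: datetime | pd.Timestamp) -> HarmonicCovariates:
    """t (continuous 24-hour clock), sin(2πt/24) and cos(2πt/24) of a timestamp."""
    ts = pd.Timestamp(timestamp)
    t = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    angle = 2.0 * np.pi * t / 24.0
    return HarmonicCovariates(t=t, s=float(np.sin(angle)), c=float(np.cos(angle)))


def harmonic_design(timestamps: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sin/cos first-harmonic terms for an array of timestamps."""
    ts = pd.DatetimeIndex(np.asarray(timestamps))
    t = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0 + ts.second.to_numpy() / 3600.0
    angle = 2.0 * np.pi * t / 24.0
    return np.sin(angle), np.cos(angle)


def _fit_glsar(y: np.ndarray, X: np.ndarray, ar_order: int):
    """GLS with AR(p) errors; ar_order=0 collapses to ordinary least squares."""
    if ar_order == 0:
        return sm.OLS(y, X).fit(), 0.0
    model = sm.GLSAR(y, X, rho=ar_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.iterative_fit(maxiter=_AR_MAX_ITER, rtol=_AR_CONVERGENCE_RTOL)
    rho = float(np.asarray(model.rho).ravel()[0])
    if not np.all(np.isfinite(res.bse)):
        raise FitError("GLS-AR fit produced non-finite standard errors")
    if not abs(rho) < 1:
        raise FitError(f"estimated AR coefficient out of range: rho={rho:.4f}")
    return res, rho


def fit_mets_model(
    series: ParticipantSeries,
    calendar: LockdownCalendar,
    min_minutes_per_state: int = MIN_MINUTES_PER_STATE,
    ar_order: int = 1,
    include_harmonics: bool = True,
) -> ModelFit:
    """Minute-level log-MET model with harmonic adjustment and AR errors.

    Design: intercept, L, sin, cos, L x sin, L x cos; the reported coefficient
    is L's, whose antilog is the post/pre ratio of geometric-mean minute METs
    at the harmonic reference.  ``series`` must already be waking-filtered
    (every minute has METs > 0 by construction of the MET scale).
    ``include_harmonics=False`` drops the time-of-day terms (used to quantify
    how much the adjustment absorbs wear-habit shifts).
    """
    df = series.records
    L = calendar.indicator_array(df["timestamp"])
    n_pre, n_post = int((L == 0).sum()), int((L == 1).sum())
    if min(n_pre, n_post) < min_minutes_per_state:
        raise FitError(
            f"{series.participant_id}/mets: need >= {min_minutes_per_state} minutes "
            f"per state, have pre={n_pre}, post={n_post}"
        )
    mets = df["mets"].to_numpy()
    if (mets <= 0).any():
        raise FitError("log-MET model requires strictly positive MET values")
    if include_harmonics:
        s, c = harmonic_design(df["timestamp"])
        X = np.column_stack([np.ones(len(df)), L, s, c, L * s, L * c])
    else:
        X = np.column_stack([np.ones(len(df)), L])
    res, rho = _fit_glsar(np.log(mets), X, ar_order)
    return ModelFit(
        participant_id=series.participant_id,
        outcome="mets",
        beta_lockdown=float(res.params[1]),
        se=float(res.bse[1]),
        n_obs=int(len(df)),
        rho=rho if ar_order else None,
    )


def _check_states(lockdown: np.ndarray, minimum: int, label: str) -> None:
    n_pre, n_post = int((lockdown == 0).sum()), int((lockdown == 1).sum())
    if min(n_pre, n_post) < minimum:
        raise FitError(
            f"{label}: need >= {minimum} observations per lockdown state, "
            f"have pre={n_pre}, post={n_post}"
        )


def _wear_column(dailies: pd.DataFrame, wear_adjust: str, log: bool) -> np.ndarray | None:
    if wear_adjust == "none":
        return None
    if wear_adjust != "wear":
        raise ValueError(f"unknown wear_adjust mode {wear_adjust!r}")
    wear = dailies["wear_minutes"].to_numpy(dtype=float)
    col = np.log(wear) if log else wear
    return col - col.mean()  # centred so the intercept stays interpretable


def fit_daily_steps_model(
    dailies: pd.DataFrame,
    participant_id: str = "",
    min_days_per_state: int = MIN_DAYS_PER_STATE,
    wear_adjust: str = "wear",
) -> ModelFit:
    """Negative-binomial regression of daily step totals on the indicator.

    Log link; covariates: intercept, L and (by default) centred log wear
    minutes.  Returns the L coefficient, its SE and the fitted dispersion
    theta (= 1/alpha in the NB2 parameterisation, variance mu + mu^2/theta).
    """
    lockdown = dailies["lockdown"].to_numpy()
    _check_states(lockdown, min_days_per_state, f"{participant_id}/steps")
    y = dailies["steps"].to_numpy(dtype=float)
    cols = [np.ones(len(dailies)), lockdown.astype(float)]
    wear = _wear_column(dailies, wear_adjust, log=True)
    if wear is not None:
        cols.append(wear)
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse[:2])):
                raise ValueError
        except Exception:
            try:
                res = model.fit(method="bfgs", disp=0, maxiter=500)
            except Exception as exc:  # pragma: no cover - diagnostics path
                raise FitError(f"{participant_id}/steps: NB fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse[:2])):
        raise FitError(f"{participant_id}/steps: NB fit non-convergent (non-finite SE)")
    alpha = float(res.params[-1])
    theta = float(1.0 / alpha) if alpha > 1e-10 else float("inf")
    return ModelFit(
        participant_id=participant_id,
        outcome="steps",
        beta_lockdown=float(res.params[1]),
        se=float(res.bse[1]),
        n_obs=int(len(dailies)),
        theta=theta,
    )


def fit_daily_intensity_model(
    dailies: pd.DataFrame,
    category: IntensityCategory,
    participant_id: str = "",
    min_days_per_state: int = MIN_DAYS_PER_STATE,
    wear_adjust: str = "wear",
    ar_order: int = 1,
    offset_minutes: float = 1.0,
    max_zero_fraction: float = 0.5,
) -> ModelFit:
    """AR(1) regression of log(category minutes + offset) on the indicator.

    The +1-minute offset keeps zero-minute days finite; days are treated as an
    equally spaced sequence for the autocorrelation structure.  Raises
    :class:`FitError` when the category is absent on more than
    ``max_zero_fraction`` of days (the log-scale effect is then dominated by
    the offset, not the behaviour).
    """
    col = OUTCOME_COLUMNS[category]
    lockdown = dailies["lockdown"].to_numpy()
    _check_states(lockdown, min_days_per_state, f"{participant_id}/{col}")
    minutes = dailies[col].to_numpy(dtype=float)
    if (minutes < 0).any():
        raise ValueError("category minutes must be non-negative")
    zero_frac = float((minutes == 0).mean())
    if zero_frac > max_zero_fraction:
        raise FitError(
            f"{participant_id}/{col}: category absent on {zero_frac:.0%} of days "
            f"(> {max_zero_fraction:.0%})"
        )
    y = np.log(minutes + offset_minutes)
    cols = [np.ones(len(dailies)), lockdown.astype(float)]
    wear = _wear_column(dailies, wear_adjust, log=False)
    if wear is not None:
        cols.append(wear)
    res, rho = _fit_glsar(y, np.column_stack(cols), ar_order)
    return ModelFit(
        participant_id=participant_id,
        outcome=col,
        beta_lockdown=float(res.params[1]),
        se=float(res.bse[1]),
        n_obs=int(len(dailies)),
        rho=rho if ar_order else None,
    )


def fit_participant_daily(
    participant_id: str,
    dailies: pd.DataFrame,
    wear_adjust: str = "wear",
    min_days_per_state: int = MIN_DAYS_PER_STATE,
    categories: Sequence[IntensityCategory] = tuple(IntensityCategory),
) -> list[ModelFit]:
    """Daily models for one participant: steps plus each intensity category."""
    fits = [
        fit_daily_steps_model(
            dailies, participant_id, min_days_per_state, wear_adjust=wear_adjust
        )
    ]
    for cat in categories:
        fits.append(
            fit_daily_intensity_model(
                dailies,
                cat,
                participant_id,
                min_days_per_state,
                wear_adjust=wear_adjust,
            )
        )
    return fits


def fit_participant(
    participant_id: str,
    filtered_series: ParticipantSeries,
    dailies: pd.DataFrame,
    calendar: LockdownCalendar,
    wear_adjust: str = "wear",
    min_days_per_state: int = MIN_DAYS_PER_STATE,
    min_minutes_per_state: int = MIN_MINUTES_PER_STATE,
) -> list[ModelFit]:
    """All six outcomes: minute-level METs plus the five daily models."""
    fits = [
        fit_mets_model(filtered_series, calendar, min_minutes_per_state=min_minutes_per_state)
    ]
    fits.extend(
        fit_participant_daily(
            participant_id, dailies, wear_adjust=wear_adjust,
            min_days_per_state=min_days_per_state,
        )
    )
    return fits


def fits_dataframe(fits: Iterable[ModelFit]) -> pd.DataFrame:
    """Tabulate fits for the delimited-text output."""
    return pd.DataFrame(
        [
            (f.participant_id, f.outcome, f.beta_lockdown, f.se, f.rho, f.theta, f.n_obs)
            for f in fits
        ],
        columns=["participant_id", "outcome", "beta", "se", "rho", "theta", "n_obs"],
    )
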