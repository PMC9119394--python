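"""Per-participant interruption models: recovery, nulls, and oracle checks."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from lockstep.activity_metrics import IntensityCategory
from lockstep.data_io import LockdownCalendar, ParticipantSeries
from lockstep.lockdown_models import (
    FitError,
    fit_daily_intensity_model,
    fit_daily_steps_model,
    fit_mets_model,
    harmonic_covariates,
)

CUTOFF = pd.Timestamp("2020-03-23")


# ---------------------------------------------------------------------------
# simulation helpers with known truth
# ---------------------------------------------------------------------------

def simulate_minute_series(
    days_pre: int,
    days_post: int,
    beta: float,
    circadian: tuple[float, float] = (0.0, 0.0),
    rho: float = 0.3,
    sd: float = 0.3,
    seed: int = 0,
    hours_pre: tuple[int, int] = (8, 18),
    hours_post: tuple[int, int] | None = None,
    base_log_met: float = np.log(1.8),
) -> ParticipantSeries:
    """Minute METs: log-linear truth exp(beta) post-cutoff, AR(1) minute noise."""
    hours_post = hours_post or hours_pre
    rng = np.random.default_rng(seed)
    frames = []
    for d in range(days_pre + days_post):
        day = CUTOFF + pd.Timedelta(days=d - days_pre)
        lockdown = int(day >= CUTOFF)
        h = hours_post if lockdown else hours_pre
        minutes = pd.date_range(
            day + pd.Timedelta(hours=h[0]), day + pd.Timedelta(hours=h[1]),
            freq="min", inclusive="left",
        )
        t = minutes.hour + minutes.minute / 60.0
        angle = 2 * np.pi * t / 24.0
        n = len(minutes)
        e = np.empty(n)
        e[0] = rng.normal(0, sd)
        innov = rng.normal(0, sd * np.sqrt(1 - rho**2), n)
        for i in range(1, n):
            e[i] = rho * e[i - 1] + innov[i]
        log_met = (
            base_log_met + beta * lockdown
            + circadian[0] * np.sin(angle) + circadian[1] * np.cos(angle) + e
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": minutes,
                    "steps": 0,
                    "mets": np.exp(log_met),
                    "heart_rate": 80,
                    "sleep_flag": False,
                }
            )
        )
    return ParticipantSeries("SIM", pd.concat(frames, ignore_index=True))


def simulate_dailies(
    n_pre: int,
    n_post: int,
    step_ratio: float = 1.0,
    sed_ratio: float = 1.0,
    theta: float = 5.0,
    sed_sd_log: float = 0.08,
    sed_rho: float = 0.0,
    seed: int = 0,
    base_steps: float = 10_000.0,
    base_sed: float = 750.0,
) -> pd.DataFrame:
    """Daily summaries with known multiplicative interruption effects."""
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    lockdown = np.r_[np.zeros(n_pre, int), np.ones(n_post, int)]
    mu = base_steps * step_ratio**lockdown
    steps = rng.negative_binomial(theta, theta / (theta + mu))
    e = np.empty(n)
    e[0] = rng.normal(0, sed_sd_log)
    innov = rng.normal(0, sed_sd_log * np.sqrt(1 - sed_rho**2), n)
    for i in range(1, n):
        e[i] = sed_rho * e[i - 1] + innov[i]
    sed = base_sed * sed_ratio**lockdown * np.exp(e)
    return pd.DataFrame(
        {
            "date": pd.date_range(CUTOFF - pd.Timedelta(days=n_pre), periods=n).date,
            "steps": steps.astype(float),
            "mets": 1800.0,
            "sedentary_min": sed,
            "light_min": 160.0,
            "fair_min": 12.0,
            "very_min": 20.0,
            "wear_minutes": 900 + rng.integers(-40, 41, n),
            "lockdown": lockdown,
        }
    )


# ---------------------------------------------------------------------------
# harmonic covariates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "hour, expected",
    [(0, (0.0, 1.0)), (6, (1.0, 0.0)), (12, (0.0, -1.0)), (18, (-1.0, 0.0))],
)
def test_harmonic_closed_forms(hour, expected):
    hc = harmonic_covariates(pd.Timestamp(f"2020-03-01 {hour:02d}:00"))
    assert hc.t == hour
    assert (hc.s, hc.c) == pytest.approx(expected, abs=1e-12)


def test_harmonic_unit_circle():
    for ts in pd.date_range("2020-03-01", periods=24 * 60, freq="min"):
        hc = harmonic_covariates(ts)
        assert hc.s**2 + hc.c**2 == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# minute-level METs model
# ---------------------------------------------------------------------------

class TestMetsModel:
    def test_recovers_known_effect_within_two_se(self, calendar):
        hits = 0
        for rep in range(20):
            series = simulate_minute_series(10, 10, beta=np.log(0.95), seed=rep)
            fit = fit_mets_model(series, calendar, min_minutes_per_state=2000)
            hits += abs(fit.beta_lockdown - np.log(0.95)) <= 2 * fit.se
        assert hits >= 18  # nominal ~95% of replicates

    def test_null_ci_covers_zero(self, calendar):
        covered = 0
        for rep in range(20):
            series = simulate_minute_series(10, 10, beta=0.0, seed=100 + rep)
            fit = fit_mets_model(series, calendar, min_minutes_per_state=2000)
            covered += abs(fit.beta_lockdown) <= 1.96 * fit.se
        assert covered >= 17

    def test_harmonics_absorb_wear_habit_shift(self, calendar):
        # pure circadian signal, no true effect, but the post period is worn
        # only 10:00-16:00: averaging over replicates, the harmonic-free fit
        # carries a systematic spurious shift while the harmonic fit does not
        betas_h, betas_free, spurious_rejections = [], [], 0
        for rep in range(10):
            series = simulate_minute_series(
                12, 12, beta=0.0, circadian=(0.3, 0.2), seed=200 + rep,
                hours_pre=(8, 18), hours_post=(10, 16),
            )
            with_h = fit_mets_model(series, calendar, min_minutes_per_state=2000)
            without_h = fit_mets_model(
                series, calendar, min_minutes_per_state=2000, include_harmonics=False
            )
            betas_h.append(with_h.beta_lockdown)
            betas_free.append(without_h.beta_lockdown)
            spurious_rejections += abs(without_h.beta_lockdown) > 1.96 * without_h.se
        assert abs(np.mean(betas_h)) < abs(np.mean(betas_free))
        assert spurious_rejections >= 8  # unadjusted model keeps "finding" an effect

    def test_antilog_invariant_to_outcome_rescaling(self, calendar):
        series = simulate_minute_series(8, 8, beta=np.log(0.9), seed=3)
        fit1 = fit_mets_model(series, calendar, min_minutes_per_state=1000)
        scaled = ParticipantSeries(
            "SIM", series.records.assign(mets=series.records["mets"] * 3.7)
        )
        fit2 = fit_mets_model(scaled, calendar, min_minutes_per_state=1000)
        assert fit2.beta_lockdown == pytest.approx(fit1.beta_lockdown, abs=1e-10)
        assert fit2.se == pytest.approx(fit1.se, rel=1e-8)

    def test_too_few_minutes_raises(self, calendar):
        series = simulate_minute_series(2, 2, beta=0.0, seed=1)
        with pytest.raises(FitError, match="per state"):
            fit_mets_model(series, calendar, min_minutes_per_state=5000)

    def test_ar_order_zero_reproduces_ols(self, calendar):
        series = simulate_minute_series(5, 5, beta=np.log(0.9), seed=9)
        fit = fit_mets_model(series, calendar, min_minutes_per_state=500, ar_order=0)
        df = series.records
        L = (df["timestamp"] >= CUTOFF).to_numpy(float)
        t = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
        angle = 2 * np.pi * t / 24.0
        s, c = np.sin(angle), np.cos(angle)
        X = np.column_stack([np.ones(len(df)), L, s, c, L * s, L * c])
        beta_ols = np.linalg.lstsq(X, np.log(df["mets"]), rcond=None)[0][1]
        assert fit.beta_lockdown == pytest.approx(beta_ols, abs=1e-10)
        assert fit.rho is None


# ---------------------------------------------------------------------------
# daily steps (negative binomial)
# ---------------------------------------------------------------------------

class TestDailyStepsModel:
    def test_recovers_rate_ratio_091(self):
        hits = 0
        for rep in range(20):
            d = simulate_dailies(100, 100, step_ratio=0.91, seed=rep)
            fit = fit_daily_steps_model(d, "SIM")
            hits += abs(fit.beta_lockdown - np.log(0.91)) <= 2 * fit.se
        assert hits >= 18

    def test_dispersion_estimate_near_truth(self):
        thetas = [
            fit_daily_steps_model(simulate_dailies(150, 150, seed=r), "SIM").theta
            for r in range(5)
        ]
        assert 3.0 < float(np.median(thetas)) < 8.0

    def test_identical_counts_give_null_coefficient(self):
        d = simulate_dailies(40, 40, seed=0)
        d["steps"] = 8000.0
        fit = fit_daily_steps_model(d, "SIM")
        assert fit.beta_lockdown == pytest.approx(0.0, abs=1e-6)

    def test_empty_state_is_a_fit_error(self):
        d = simulate_dailies(40, 40, seed=0)
        with pytest.raises(FitError, match="per lockdown state"):
            fit_daily_steps_model(d[d["lockdown"] == 0], "SIM")


# ---------------------------------------------------------------------------
# daily intensity minutes (GLS-AR)
# ---------------------------------------------------------------------------

class TestDailyIntensityModel:
    def test_recovers_sedentary_ratio_103(self):
        hits = 0
        for rep in range(20):
            d = simulate_dailies(100, 100, sed_ratio=1.03, seed=rep)
            fit = fit_daily_intensity_model(d, IntensityCategory.SEDENTARY, "SIM")
            hits += abs(fit.beta_lockdown - np.log(1.03)) <= 2 * fit.se
        assert hits >= 18

    def test_constant_minutes_give_null_coefficient(self):
        d = simulate_dailies(40, 40, seed=1)
        d["sedentary_min"] = 700.0
        fit = fit_daily_intensity_model(d, IntensityCategory.SEDENTARY, "SIM")
        assert fit.beta_lockdown == pytest.approx(0.0, abs=1e-8)

    def test_ar_aware_se_exceeds_naive_ols_se_under_autocorrelation(self):
        d = simulate_dailies(120, 120, sed_sd_log=0.15, sed_rho=0.6, seed=4)
        ar_fit = fit_daily_intensity_model(d, IntensityCategory.SEDENTARY, "SIM", ar_order=1)
        ols_fit = fit_daily_intensity_model(d, IntensityCategory.SEDENTARY, "SIM", ar_order=0)
        assert ar_fit.rho > 0.3
        assert ar_fit.se >= ols_fit.se

    def test_se_shrinks_with_more_days(self):
        small = fit_daily_intensity_model(
            simulate_dailies(60, 60, seed=6), IntensityCategory.SEDENTARY, "SIM"
        )
        large = fit_daily_intensity_model(
            simulate_dailies(240, 240, seed=6), IntensityCategory.SEDENTARY, "SIM"
        )
        assert large.se < small.se

    def test_mostly_absent_category_is_a_fit_error(self):
        d = simulate_dailies(40, 40, seed=2)
        d["very_min"] = 0.0
        with pytest.raises(FitError, match="absent"):
            fit_daily_intensity_model(d, IntensityCategory.VERY_ACTIVE, "SIM")
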