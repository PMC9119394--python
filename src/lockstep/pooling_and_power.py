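"""Fixed-effect pooling of interruption coefficients and the NB power model.

Per-participant log-scale coefficients are combined by inverse-variance
weighting under a common-effect assumption:

    w_i = 1/se_i^2,  beta = sum(w_i b_i)/sum(w_i),  se = (sum w_i)^(-1/2)

The pooled coefficient back-transforms to a relative rate rr = exp(beta) and a
percentage change delta% = 100*(rr - 1) with a normal-theory 95% CI; the
effect is declared significant when that interval excludes zero.

The power module answers the design question "how many observed days per
period detect a given step-count reduction?" for daily step totals following a
negative binomial distribution with dispersion theta (variance mu + mu^2/theta).
Analytic power uses a two-sided Wald test on the difference of log means,
whose per-group variance is (1/mu + 1/theta)/n; a Monte-Carlo mode simulates
two-group datasets and measures the rejection rate for verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .lockdown_models import ModelFit

__all__ = [
    "PooledEffect",
    "PowerSpec",
    "pool_fixed_effect",
    "to_delta_percent",
    "nb_power",
    "pooled_effect_row",
]

Z_975 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PooledEffect:
    """Cohort-level interruption effect for one outcome."""

    outcome: str
    beta_pooled: float
    se_pooled: float
    rr: float
    delta_pct: float
    ci95: tuple[float, float]  # percent scale
    significant: bool
    n_participants: int


@dataclass(frozen=True)
class PowerSpec:
    """Two-group negative-binomial design (all days pooled within group)."""

    mu1: float  # pre-period mean daily steps
    ratio: float  # post/pre mean ratio under the alternative
    theta: float  # NB dispersion
    n_per_group: int  # observed days per group
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.ratio <= 0 or self.theta <= 0:
            raise ValueError("mu1, ratio and theta must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def to_delta_percent(beta: float, se: float) -> tuple[float, float, tuple[float, float]]:
    """Relative rate, delta% and 95% CI (percent scale) of a log coefficient."""
    if se < 0:
        raise ValueError("se must be non-negative")
    rr = float(np.exp(beta))
    lo = 100.0 * (np.exp(beta - Z_975 * se) - 1.0)
    hi = 100.0 * (np.exp(beta + Z_975 * se) - 1.0)
    return rr, 100.0 * (rr - 1.0), (float(lo), float(hi))


def pool_fixed_effect(fits: Sequence[ModelFit]) -> PooledEffect:
    """Inverse-variance (fixed-effect) pooling of one outcome across participants.

    All fits must address the same outcome and carry positive SEs.  The
    significance flag applies the zero-interception rule to the delta% CI.
    """
    if len(fits) == 0:
        raise ValueError("pool_fixed_effect requires at least one fit")
    outcomes = {f.outcome for f in fits}
    if len(outcomes) != 1:
        raise ValueError(f"fits mix outcomes: {sorted(outcomes)}")
    beta = np.array([f.beta_lockdown for f in fits])
    se = np.array([f.se for f in fits])
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    beta_pooled = float((w * beta).sum() / w.sum())
    se_pooled = float(w.sum() ** -0.5)
    rr, delta, ci = to_delta_percent(beta_pooled, se_pooled)
    return PooledEffect(
        outcome=fits[0].outcome,
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        rr=rr,
        delta_pct=delta,
        ci95=ci,
        significant=not (ci[0] <= 0.0 <= ci[1]),
        n_participants=len(fits),
    )


def pooled_effect_row(effect: PooledEffect) -> dict:
    """Flatten a pooled effect for the delimited-text table."""
    return {
        "outcome": effect.outcome,
        "beta": effect.beta_pooled,
        "se": effect.se_pooled,
        "rr": effect.rr,
        "delta_pct": effect.delta_pct,
        "ci_low_pct": effect.ci95[0],
        "ci_high_pct": effect.ci95[1],
        "significant": effect.significant,
        "n_participants": effect.n_participants,
    }


# ---------------------------------------------------------------------------
# Negative-binomial power
# ---------------------------------------------------------------------------

def _log_mean_var(mu: float, theta: float, n: int) -> float:
    # Delta-method variance of the log of a group mean of NB(mu, theta) draws:
    # Var(ybar)/mu^2 = (mu + mu^2/theta)/(n mu^2) = (1/mu + 1/theta)/n.
    return (1.0 / mu + 1.0 / theta) / n


def nb_power(
    spec: PowerSpec,
    method: str = "analytic",
    n_reps: int = 5_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Power of the two-sided two-group NB comparison at level alpha.

    ``method="analytic"`` evaluates the Wald power in closed form; under the
    null ratio = 1 it returns approximately alpha.  ``method="monte-carlo"``
    simulates ``n_reps`` two-group datasets from the alternative, applies a
    Wald test on the difference of log sample means (variance plugged in from
    the sample means and a method-of-moments dispersion estimate), and returns
    the rejection rate.
    """
    mu2 = spec.mu1 * spec.ratio
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    if method == "analytic":
        sd = np.sqrt(
            _log_mean_var(spec.mu1, spec.theta, spec.n_per_group)
            + _log_mean_var(mu2, spec.theta, spec.n_per_group)
        )
        shift = abs(np.log(spec.ratio)) / sd
        return float(
            stats.norm.cdf(shift - z_alpha) + stats.norm.cdf(-shift - z_alpha)
        )
    if method != "monte-carlo":
        raise ValueError(f"unknown power method {method!r}")
    rng = rng or np.random.default_rng()
    n = spec.n_per_group
    y1 = rng.negative_binomial(
        spec.theta, spec.theta / (spec.theta + spec.mu1), size=(n_reps, n)
    )
    y2 = rng.negative_binomial(
        spec.theta, spec.theta / (spec.theta + mu2), size=(n_reps, n)
    )
    rejections = 0
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1, v2 = y1.var(axis=1, ddof=1), y2.var(axis=1, ddof=1)
    # Method-of-moments theta per group: var = mu + mu^2/theta.
    with np.errstate(divide="ignore", invalid="ignore"):
        th1 = np.where(v1 > m1, m1**2 / (v1 - m1), np.inf)
        th2 = np.where(v2 > m2, m2**2 / (v2 - m2), np.inf)
    var_log = (1.0 / m1 + 1.0 / th1) / n + (1.0 / m2 + 1.0 / th2) / n
    z = (np.log(m2) - np.log(m1)) / np.sqrt(var_log)
    return float((np.abs(z) > z_alpha).mean())
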