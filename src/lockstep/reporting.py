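"""Publication-style outputs: the period-comparison summary table and the
minute-by-day intensity heat-map matrix.

The summary table mirrors the usual layout of interruption studies: one row
per outcome with pre-period mean (SD), during-period mean (SD), their
difference, and the pooled delta% with 95% CI.  Display rounding is applied
*before* the difference column is formed (steps, METs and minutes to integers;
bout durations to one decimal; delta% to integers), so the printed difference
is exactly reproducible from the printed means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity_metrics import (
    IntensityCategory,
    NoBoutsError,
    bouts_for_series,
    usual_bout_duration,
)
from .data_io import LockdownCalendar, ParticipantSeries
from .pooling_and_power import PooledEffect
from .waking_filter import WakingDay

__all__ = [
    "SummaryRow",
    "ReportError",
    "make_summary_row",
    "summary_table",
    "participant_w50_table",
    "summary_rows_dataframe",
    "format_summary_table",
    "intensity_heatmap_matrix",
    "HeatmapMatrix",
    "NOT_WORN_CODE",
]

#: Heat-map cell code for removed (sleep / overnight / not-worn) minutes.
NOT_WORN_CODE = -1


class ReportError(ValueError):
    """Raised when summaries and pooled effects cannot be matched."""


#: (outcome key, display label, decimals for means) in table order.
TABLE_ROWS: tuple[tuple[str, str, int], ...] = (
    ("steps", "Steps (n/day)", 0),
    ("mets", "METs (n/day)", 0),
    ("light_min", "Lightly active intensity (mins/day)", 0),
    ("fair_min", "Fairly active intensity (mins/day)", 0),
    ("very_min", "Very active intensity (mins/day)", 0),
    ("sedentary_min", "Sedentary (mins/day)", 0),
    ("w50_light", "Usual bout duration, lightly active (mins)", 1),
    ("w50_fair", "Usual bout duration, fairly active (mins)", 1),
    ("w50_very", "Usual bout duration, very active (mins)", 1),
    ("w50_sedentary", "Usual bout duration, sedentary (mins)", 1),
)

_W50_KEYS = {
    IntensityCategory.SEDENTARY: "w50_sedentary",
    IntensityCategory.LIGHTLY_ACTIVE: "w50_light",
    IntensityCategory.FAIRLY_ACTIVE: "w50_fair",
    IntensityCategory.VERY_ACTIVE: "w50_very",
}

_DAILY_KEYS = {
    "steps": "steps",
    "mets": "mets",
    "sedentary_min": "sedentary_min",
    "light_min": "light_min",
    "fair_min": "fair_min",
    "very_min": "very_min",
}


@dataclass(frozen=True)
class SummaryRow:
    """One outcome row of the period-comparison table (display-rounded)."""

    label: str
    mean_pre: float
    sd_pre: float
    mean_during: float
    sd_during: float
    difference: float
    delta_pct: float | None
    ci95: tuple[float, float] | None
    significant: bool | None


def _round(x: float, decimals: int) -> float:
    return float(np.round(x, decimals)) if decimals else float(np.round(x))


def make_summary_row(
    label: str,
    mean_pre: float,
    sd_pre: float,
    mean_during: float,
    sd_during: float,
    pooled: PooledEffect | None = None,
    decimals: int = 0,
) -> SummaryRow:
    """Build one display row; the difference is formed from the rounded means."""
    mp = _round(mean_pre, decimals)
    md = _round(mean_during, decimals)
    diff = _round(md - mp, decimals)
    if pooled is None:
        delta = ci = sig = None
    else:
        delta = float(np.round(pooled.delta_pct))
        ci = (float(np.round(pooled.ci95[0])), float(np.round(pooled.ci95[1])))
        sig = pooled.significant
    return SummaryRow(
        label=label,
        mean_pre=mp,
        sd_pre=_round(sd_pre, decimals),
        mean_during=md,
        sd_during=_round(sd_during, decimals),
        difference=diff,
        delta_pct=delta,
        ci95=ci,
        significant=sig,
    )


def _period_stats(
    dailies_by_participant: Mapping[str, pd.DataFrame], column: str, period: int
) -> tuple[float, float]:
    """Across-participant mean and SD of per-participant period means."""
    means = []
    for df in dailies_by_participant.values():
        sub = df[df["lockdown"] == period]
        if len(sub):
            means.append(float(sub[column].mean()))
    if not means:
        raise ReportError(f"no observations for {column!r} in period {period}")
    arr = np.asarray(means)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def participant_w50_table(
    days: Sequence[WakingDay], calendar: LockdownCalendar
) -> pd.DataFrame:
    """Per-period usual bout durations for one participant.

    Bouts are accumulated over all the participant's waking days in each
    period before the weighted median is taken (w50 is invariant to how the
    bout list was split across days).  Categories with no bouts in a period
    are omitted.
    """
    rows = []
    for period in (0, 1):
        period_days = [d for d in days if calendar.indicator(d.date) == period]
        bouts = bouts_for_series(period_days)
        for cat in IntensityCategory:
            try:
                ubd = usual_bout_duration(bouts, cat)
            except NoBoutsError:
                continue
            rows.append((cat.value, period, ubd.w50, ubd.total_category_minutes))
    return pd.DataFrame(rows, columns=["category", "lockdown", "w50", "total_minutes"])


def _w50_period_stats(
    w50_by_participant: Mapping[str, pd.DataFrame], category: IntensityCategory, period: int
) -> tuple[float, float]:
    vals = []
    for df in w50_by_participant.values():
        sub = df[(df["category"] == category.value) & (df["lockdown"] == period)]
        if len(sub):
            vals.append(float(sub["w50"].iloc[0]))
    if not vals:
        raise ReportError(f"no w50 values for {category.value} in period {period}")
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def summary_table(
    dailies_by_participant: Mapping[str, pd.DataFrame],
    pooled: Mapping[str, PooledEffect] | Sequence[PooledEffect],
    w50_by_participant: Mapping[str, pd.DataFrame] | None = None,
) -> list[SummaryRow]:
    """Assemble the full period-comparison table.

    Period means are across-participant means of per-participant period
    means; delta%/CI come from the pooled effects (never recomputed from the
    raw means).  Rows whose outcome has no pooled effect carry None there;
    an outcome present in ``pooled`` but lacking summaries raises
    :class:`ReportError`.
    """
    if not isinstance(pooled, Mapping):
        pooled = {p.outcome: p for p in pooled}
    available = set(_DAILY_KEYS) | (set(k for k in _W50_KEYS.values()) if w50_by_participant else set())
    unmatched = set(pooled) - available
    if unmatched:
        raise ReportError(f"pooled outcomes without matching summaries: {sorted(unmatched)}")
    rows = []
    for key, label, decimals in TABLE_ROWS:
        if key in _DAILY_KEYS:
            pre = _period_stats(dailies_by_participant, _DAILY_KEYS[key], 0)
            dur = _period_stats(dailies_by_participant, _DAILY_KEYS[key], 1)
        elif w50_by_participant is not None:
            cat = next(c for c, k in _W50_KEYS.items() if k == key)
            try:
                pre = _w50_period_stats(w50_by_participant, cat, 0)
                dur = _w50_period_stats(w50_by_participant, cat, 1)
            except ReportError:
                continue
        else:
            continue
        rows.append(
            make_summary_row(label, pre[0], pre[1], dur[0], dur[1], pooled.get(key), decimals)
        )
    return rows


def summary_table_from_frames(
    per_participant: Mapping[str, tuple],
    pooled_frame: pd.DataFrame,
    w50_by_participant: Mapping[str, pd.DataFrame] | None = None,
) -> list[SummaryRow]:
    """CLI adapter: build the table from (filtered, dailies) pairs and the
    pooled-effects CSV written by the fit step."""
    pooled: dict[str, PooledEffect] = {}
    for _, r in pooled_frame.iterrows():
        pooled[str(r["outcome"])] = PooledEffect(
            outcome=str(r["outcome"]),
            beta_pooled=float(r["beta"]),
            se_pooled=float(r["se"]),
            rr=float(r["rr"]),
            delta_pct=float(r["delta_pct"]),
            ci95=(float(r["ci_low_pct"]), float(r["ci_high_pct"])),
            significant=bool(r["significant"]),
            n_participants=int(r["n_participants"]),
        )
    dailies = {pid: d for pid, (_f, d) in per_participant.items()}
    return summary_table(dailies, pooled, w50_by_participant)


def summary_rows_dataframe(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.label,
                r.mean_pre,
                r.sd_pre,
                r.mean_during,
                r.sd_during,
                r.difference,
                r.delta_pct,
                None if r.ci95 is None else r.ci95[0],
                None if r.ci95 is None else r.ci95[1],
                r.significant,
            )
            for r in rows
        ],
        columns=[
            "outcome",
            "mean_pre",
            "sd_pre",
            "mean_during",
            "sd_during",
            "difference",
            "delta_pct",
            "ci_low_pct",
            "ci_high_pct",
            "significant",
        ],
    )


def format_summary_table(rows: Iterable[SummaryRow]) -> str:
    """Aligned plain-text rendering of the summary table."""
    lines = [
        f"{'Outcome':44s} {'Pre mean (SD)':>18s} {'During mean (SD)':>18s} "
        f"{'Diff':>8s} {'Δ% (95% CI)':>20s}"
    ]
    for r in rows:
        delta = (
            f"{r.delta_pct:.0f} ({r.ci95[0]:.0f} to {r.ci95[1]:.0f})"
            if r.delta_pct is not None
            else "—"
        )
        mark = "*" if r.significant else ""
        lines.append(
            f"{r.label:44s} {f'{r.mean_pre:g} ({r.sd_pre:g})':>18s} "
            f"{f'{r.mean_during:g} ({r.sd_during:g})':>18s} {r.difference:>8g} "
            f"{delta + mark:>20s}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Heat map
# ---------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    """Day x minute-of-day intensity matrix for one participant.

    ``matrix[d, m]`` holds the category code (0..3) of minute m on day d, or
    :data:`NOT_WORN_CODE` where the minute was removed or unrecorded.
    ``cutoff_row`` is the row index of the first day on/after the cutoff date
    (None when no calendar was supplied or the window ends before it).
    """

    participant_id: str
    dates: list
    matrix: np.ndarray  # (n_days, 1440), int8
    cutoff_row: int | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.dates, name="date"))

    def plot(self, ax=None):
        """Optional raster rendering (red/green/blue/cyan over black)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        cmap = ListedColormap(["black", "red", "green", "blue", "cyan"])
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 6))
        ax.imshow(self.matrix + 1, aspect="auto", cmap=cmap, vmin=0, vmax=4,
                  interpolation="nearest")
        if self.cutoff_row is not None:
            ax.axhline(self.cutoff_row - 0.5, color="yellow", lw=1.5)
        ax.set_xlabel("minute of day")
        ax.set_ylabel(f"day of observation — {self.participant_id}")
        return ax


def intensity_heatmap_matrix(
    series: ParticipantSeries,
    calendar: LockdownCalendar | None = None,
) -> HeatmapMatrix:
    """Rasterise a waking-filtered series into a day x 1,440-minute matrix.

    Rows cover every calendar day from the first to the last retained minute;
    cells of removed/missing minutes carry the not-worn code, so per-row
    counts of category cells equal each day's wear minutes.
    """
    from .activity_metrics import classify_minutes

    df = series.records
    if len(df) == 0:
        raise ValueError("cannot rasterise an empty series")
    ts = df["timestamp"]
    day_idx = (ts.dt.normalize() - ts.dt.normalize().min()).dt.days.to_numpy()
    minute_idx = (ts.dt.hour * 60 + ts.dt.minute).to_numpy()
    n_days = int(day_idx.max()) + 1
    matrix = np.full((n_days, 1440), NOT_WORN_CODE, dtype=np.int8)
    matrix[day_idx, minute_idx] = classify_minutes(df["mets"].to_numpy())
    start = pd.Timestamp(ts.min()).normalize()
    dates = [(start + pd.Timedelta(days=int(d))).date() for d in range(n_days)]
    cutoff_row = None
    if calendar is not None:
        hits = [i for i, d in enumerate(dates) if calendar.indicator(d) == 1]
        cutoff_row = hits[0] if hits else None
    return HeatmapMatrix(
        participant_id=series.participant_id,
        dates=dates,
        matrix=matrix,
        cutoff_row=cutoff_row,
    )
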