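"""Reading and writing minute-level tracker exports, configuration, and the CLI.

Consumer trackers synced through third-party export services (Fitabase-style)
deliver per-minute tables: a timestamp column plus steps, METs and heart rate,
with sleep delivered either as a per-minute flag or as separate (start, end)
intervals.  This module reads those tables into :class:`ParticipantSeries`
frames, writes every pipeline output, and hosts the command-line entry point.

A heart rate of 0 encodes "device not worn" and is preserved on ingest; the
waking filter interprets it downstream.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MINUTE_COLUMNS",
    "FormatError",
    "DataError",
    "FitabaseDialect",
    "ParticipantSeries",
    "LockdownCalendar",
    "read_fitabase_minutes",
    "write_fitabase_minutes",
    "read_sleep_intervals",
    "attach_sleep_records",
    "load_config",
    "run_cli",
    "main",
]

#: Canonical column order of the in-memory minute frame.
MINUTE_COLUMNS = ("timestamp", "steps", "mets", "heart_rate", "sleep_flag")


class FormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class DataError(ValueError):
    """A file parses but violates a data invariant (e.g. duplicate minutes)."""


@dataclass(frozen=True)
class FitabaseDialect:
    """Column naming and numeric encoding of a minute-level export.

    ``met_scale`` divides the raw MET column on ingest: the common Fitabase
    minute-MET export stores integer METs at x10 scale, so the default is 10;
    set 1 for files holding raw MET values.  ``sleep_col`` names an optional
    per-minute boolean sleep column; when absent, sleep is attached from a
    separate interval file via :func:`attach_sleep_records`.
    """

    delimiter: str = ","
    timestamp_col: str = "ActivityMinute"
    steps_col: str = "Steps"
    mets_col: str = "METs"
    heart_rate_col: str = "HeartRate"
    sleep_col: str | None = None
    met_scale: float = 10.0
    timestamp_format: str | None = None  # None -> pandas-inferred


#: Dialect used for files this package writes itself (raw METs, ISO stamps).
CANONICAL_DIALECT = FitabaseDialect(met_scale=1.0, timestamp_format="%Y-%m-%d %H:%M:%S")


@dataclass
class ParticipantSeries:
    """One participant's ordered minute-level record stream.

    ``records`` holds the columns in :data:`MINUTE_COLUMNS`; timestamps are
    strictly increasing, minute-aligned local wall-clock times.
    """

    participant_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in MINUTE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"records frame missing columns: {missing}")
        if len(df) == 0:
            raise DataError(f"participant {self.participant_id}: empty record stream")
        ts = df["timestamp"].to_numpy().astype("datetime64[m]")
        if (df["timestamp"].to_numpy() != ts).any():
            raise DataError("timestamps must be aligned to whole minutes")
        delta = np.diff(ts.astype(np.int64))
        if (delta <= 0).any():
            i = int(np.argmax(delta <= 0)) + 1
            raise DataError(
                f"participant {self.participant_id}: timestamps not strictly "
                f"increasing at row {i} ({df['timestamp'].iloc[i]})"
            )
        for col in ("steps", "mets", "heart_rate"):
            if (df[col].to_numpy() < 0).any():
                raise DataError(f"negative values in column {col!r}")

    @property
    def observation_start(self) -> date:
        return pd.Timestamp(self.records["timestamp"].iloc[0]).date()

    @property
    def observation_end(self) -> date:
        return pd.Timestamp(self.records["timestamp"].iloc[-1]).date()

    def replace_records(self, records: pd.DataFrame) -> "ParticipantSeries":
        return ParticipantSeries(self.participant_id, records)


@dataclass(frozen=True)
class LockdownCalendar:
    """Binary interruption indicator: 0 strictly before the cutoff date, 1 after.

    The cutoff is a calendar date (the paper-style convention "on or after the
    cutoff counts as during").
    """

    cutoff_date: date

    def indicator(self, d: date | datetime | pd.Timestamp) -> int:
        if isinstance(d, (datetime, pd.Timestamp)):
            d = pd.Timestamp(d).date()
        return int(d >= self.cutoff_date)

    def indicator_array(self, dates: np.ndarray | pd.Series) -> np.ndarray:
        """Vectorised indicator over an array of datetimes or dates."""
        arr = pd.DatetimeIndex(pd.to_datetime(np.asarray(dates))).normalize()
        return np.asarray(arr >= pd.Timestamp(self.cutoff_date), dtype=int)


# ---------------------------------------------------------------------------
# Minute files
# ---------------------------------------------------------------------------

def read_fitabase_minutes(
    path: str | Path,
    dialect: FitabaseDialect = FitabaseDialect(),
    participant_id: str | None = None,
) -> ParticipantSeries:
    """Read one participant's minute-level export.

    Raises :class:`FormatError` when a required column is absent and
    :class:`DataError` for duplicated or non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.delimiter)
    required = {
        dialect.timestamp_col: "timestamp",
        dialect.steps_col: "steps",
        dialect.mets_col: "mets",
        dialect.heart_rate_col: "heart_rate",
    }
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    df = raw.rename(columns=required)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format=dialect.timestamp_format)
    df["steps"] = df["steps"].astype(np.int64)
    df["mets"] = df["mets"].astype(float) / dialect.met_scale
    df["heart_rate"] = df["heart_rate"].astype(np.int64)
    if dialect.sleep_col is not None:
        if dialect.sleep_col not in raw.columns:
            raise FormatError(f"{path.name}: missing sleep column {dialect.sleep_col!r}")
        df["sleep_flag"] = raw[dialect.sleep_col].astype(bool)
    else:
        df["sleep_flag"] = False
    df = df[list(MINUTE_COLUMNS)]
    return ParticipantSeries(participant_id or path.stem, df)


def write_fitabase_minutes(
    series: ParticipantSeries,
    path: str | Path,
    dialect: FitabaseDialect = CANONICAL_DIALECT,
) -> None:
    """Write a series back out in the given dialect (inverse of the reader)."""
    df = series.records
    out = pd.DataFrame(
        {
            dialect.timestamp_col: df["timestamp"].dt.strftime(
                dialect.timestamp_format or "%Y-%m-%d %H:%M:%S"
            ),
            dialect.steps_col: df["steps"],
            dialect.mets_col: (df["mets"] * dialect.met_scale),
            dialect.heart_rate_col: df["heart_rate"],
        }
    )
    if dialect.met_scale != 1.0:
        out[dialect.mets_col] = out[dialect.mets_col].round().astype(np.int64)
    if dialect.sleep_col is not None:
        out[dialect.sleep_col] = df["sleep_flag"].astype(int)
    out.to_csv(path, sep=dialect.delimiter, index=False)


def read_sleep_intervals(path: str | Path) -> dict[str, list[tuple[datetime, datetime]]]:
    """Read a sleep-interval table (participant_id, start, end) keyed by participant."""
    df = pd.read_csv(path)
    for col in ("participant_id", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    out: dict[str, list[tuple[datetime, datetime]]] = {}
    for pid, grp in df.groupby("participant_id"):
        out[str(pid)] = [
            (pd.Timestamp(s).to_pydatetime(), pd.Timestamp(e).to_pydatetime())
            for s, e in zip(grp["start"], grp["end"])
        ]
    return out


def attach_sleep_records(
    series: ParticipantSeries,
    sleep_intervals: Sequence[tuple[datetime, datetime]],
) -> ParticipantSeries:
    """Set sleep_flag for every minute inside any interval (closed-open).

    A minute stamped t is flagged iff start <= t < end for some interval.
    Overlapping intervals are merged implicitly (flag union).  Idempotent:
    re-attaching the same intervals changes nothing.
    """
    for s, e in sleep_intervals:
        if not s < e:
            raise DataError(f"malformed sleep interval: start {s} !< end {e}")
    df = series.records.copy()
    flag = np.zeros(len(df), dtype=bool)
    ts = df["timestamp"].to_numpy()
    for s, e in sleep_intervals:
        flag |= (ts >= np.datetime64(s)) & (ts < np.datetime64(e))
    df["sleep_flag"] = flag
    return series.replace_records(df)


def read_cohort_dir(
    directory: str | Path,
    dialect: FitabaseDialect = CANONICAL_DIALECT,
    sleep_file: str | Path | None = None,
) -> list[ParticipantSeries]:
    """Read every ``*_minutes.csv`` file in a directory as one participant each."""
    directory = Path(directory)
    paths = sorted(directory.glob("*_minutes.csv"))
    if not paths:
        raise FileNotFoundError(f"no *_minutes.csv files in {directory}")
    sleep = read_sleep_intervals(sleep_file) if sleep_file else {}
    cohort = []
    for p in paths:
        pid = p.stem.removesuffix("_minutes")
        series = read_fitabase_minutes(p, dialect, participant_id=pid)
        if pid in sleep:
            series = attach_sleep_records(series, sleep[pid])
        cohort.append(series)
    return cohort


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cutoff_date": "2020-03-23",
    "dialect": {"met_scale": 1.0},
    "filter": {"min_wear_minutes": 0},
    "models": {"wear_adjust": "wear", "ar_order": 1},
    "simulate": {},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, overlaying :data:`DEFAULT_CONFIG`."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _calendar_from_config(cfg: Mapping) -> LockdownCalendar:
    return LockdownCalendar(pd.Timestamp(cfg["cutoff_date"]).date())


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group(name="lockstep")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML configuration file.")
@click.pass_context
def cli(ctx: click.Context, config_path: str | None) -> None:
    """Wearable-activity interruption analysis pipeline."""
    ctx.obj = load_config(config_path)


@cli.command()
@click.option("--n", "n_participants", type=int, default=None, help="Cohort size.")
@click.option("--seed", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.pass_obj
def simulate(cfg: dict, n_participants: int | None, seed: int | None, outdir: str) -> None:
    """Generate a synthetic cohort and write one minute file per participant."""
    from . import synthetic_cohort as sc

    sim = dict(cfg.get("simulate") or {})
    if n_participants is not None:
        sim["n_participants"] = n_participants
    if seed is not None:
        sim["seed"] = seed
    if "cutoff_date" not in sim:
        sim["cutoff_date"] = pd.Timestamp(cfg["cutoff_date"]).date()
    config = sc.SimulationConfig(**sim)
    cohort = sc.generate_cohort(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for series in cohort:
        write_fitabase_minutes(series, out / f"{series.participant_id}_minutes.csv")
    manifest = {
        "command": "simulate",
        "n_participants": config.n_participants,
        "seed": config.seed,
        "cutoff_date": str(config.cutoff_date),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    click.echo(f"wrote {len(cohort)} participant files to {out}")


def _process_cohort(cfg: dict, indir: str):
    from . import waking_filter as wf
    from .activity_metrics import daily_summaries

    dialect = FitabaseDialect(**{**{"met_scale": 1.0, "timestamp_format": None},
                                 **(cfg.get("dialect") or {})})
    calendar = _calendar_from_config(cfg)
    min_wear = int(cfg["filter"].get("min_wear_minutes", 0))
    cohort = read_cohort_dir(indir, dialect)
    per_participant = {}
    for series in cohort:
        filtered = wf.define_waking_minutes(series)
        days = [d for d in wf.split_into_days(filtered, min_wear) if d.valid]
        per_participant[series.participant_id] = (filtered, daily_summaries(days, calendar))
    return calendar, per_participant


@cli.command()
@click.option("--in", "indir", type=click.Path(exists=True), required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.pass_obj
def process(cfg: dict, indir: str, outdir: str) -> None:
    """Filter to waking worn minutes and write per-day summary tables."""
    _, per_participant = _process_cohort(cfg, indir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for pid, (_f, dailies) in per_participant.items():
        dailies = dailies.copy()
        dailies.insert(0, "participant_id", pid)
        frames.append(dailies)
    pd.concat(frames).to_csv(out / "daily_summaries.csv", index=False)
    click.echo(f"wrote daily summaries for {len(frames)} participants to {out}")


@cli.command()
@click.option("--in", "indir", type=click.Path(exists=True), required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.pass_obj
def fit(cfg: dict, indir: str, outdir: str) -> None:
    """Fit per-participant interruption models and pool across the cohort."""
    from . import lockdown_models as lm
    from . import pooling_and_power as pp

    calendar, per_participant = _process_cohort(cfg, indir)
    wear_adjust = cfg["models"].get("wear_adjust", "wear")
    fits = []
    for pid, (filtered, dailies) in per_participant.items():
        fits.extend(
            lm.fit_participant(pid, filtered, dailies, calendar, wear_adjust=wear_adjust)
        )
    fit_df = lm.fits_dataframe(fits)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fit_df.to_csv(out / "participant_fits.csv", index=False)
    pooled_rows = []
    for outcome, grp in fit_df.groupby("outcome"):
        subset = [f for f in fits if f.outcome == outcome]
        pooled_rows.append(pp.pooled_effect_row(pp.pool_fixed_effect(subset)))
    pd.DataFrame(pooled_rows).to_csv(out / "pooled_effects.csv", index=False)
    click.echo(f"wrote {len(fit_df)} fits and {len(pooled_rows)} pooled effects to {out}")


@cli.command()
@click.option("--in", "indir", type=click.Path(exists=True), required=True,
              help="Directory produced by `fit` (pooled_effects.csv) plus minute files.")
@click.option("--minutes", "minutes_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.pass_obj
def report(cfg: dict, indir: str, minutes_dir: str, outdir: str) -> None:
    """Write the summary table and per-participant intensity heat-map matrices."""
    from . import reporting

    from . import waking_filter as wf

    calendar, per_participant = _process_cohort(cfg, minutes_dir)
    pooled = pd.read_csv(Path(indir) / "pooled_effects.csv")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    min_wear = int(cfg["filter"].get("min_wear_minutes", 0))
    w50_tables = {
        pid: reporting.participant_w50_table(
            [d for d in wf.split_into_days(filtered, min_wear) if d.valid], calendar
        )
        for pid, (filtered, _dailies) in per_participant.items()
    }
    table = reporting.summary_table_from_frames(per_participant, pooled, w50_tables)
    reporting.summary_rows_dataframe(table).to_csv(out / "summary_table.csv", index=False)
    (out / "summary_table.txt").write_text(reporting.format_summary_table(table))
    for pid, (filtered, _dailies) in per_participant.items():
        mat = reporting.intensity_heatmap_matrix(filtered)
        mat.frame().to_csv(out / f"{pid}_heatmap.csv")
    click.echo(f"wrote summary table and {len(per_participant)} heat maps to {out}")


@cli.command()
@click.option("--mu1", type=float, default=10_000.0, show_default=True)
@click.option("--ratio", type=float, default=0.9, show_default=True)
@click.option("--theta", type=float, default=5.0, show_default=True)
@click.option("--n-per-group", type=int, default=1_100, show_default=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
def power(mu1: float, ratio: float, theta: float, n_per_group: int, alpha: float) -> None:
    """Analytic power for the two-group negative-binomial comparison."""
    from .pooling_and_power import PowerSpec, nb_power

    spec = PowerSpec(mu1=mu1, ratio=ratio, theta=theta, n_per_group=n_per_group, alpha=alpha)
    result = nb_power(spec)
    click.echo(json.dumps({**dataclasses.asdict(spec), "power": result}, indent=2))


def run_cli(argv: Sequence[str]) -> int:
    """Programmatic CLI entry point: returns the process exit status."""
    try:
        cli.main(args=list(argv), standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except click.exceptions.Abort:
        return 1
    except SystemExit as exc:  # click may still raise on --help
        return int(exc.code or 0)
    except (FileNotFoundError, DataError, FormatError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 2


def main() -> None:  # console-script shim
    sys.exit(run_cli(sys.argv[1:]))
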