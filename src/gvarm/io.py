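"""Reading, writing and sleep-aware segmentation of CGM data.

The native CSV dialect has columns ``subject_id,timestamp,glucose_mgdl``
with ISO-8601 timestamps; a FreeStyle-Libre-style export (columns
``Device Timestamp`` / ``Historic Glucose mg/dL``) is detected and
mapped automatically. Sleep logs (Fitbit-style) carry
``subject_id,onset,offset``.

Segmentation splits each subject's series into one in-sleep and one
awake segment per day. A sleep episode belongs to the calendar date of
its *offset* (the morning it ends); the awake segment of day N spans
from that day's sleep offset to the onset of the next day's sleep.
Windows are closed at their start instant and open at their end, so a
reading falling exactly on a sleep onset belongs to the sleep segment
and no reading is ever double-counted.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, GvarmError

logger = logging.getLogger(__name__)

#: mg/dl per mmol/L, for the unit-conversion adapter.
MGDL_PER_MMOL = 18.016

#: Column mapping for FreeStyle-Libre-style exports.
LIBRE_COLUMNS = {
    "Device Timestamp": "timestamp",
    "Historic Glucose mg/dL": "glucose_mgdl",
}


def mgdl_to_mmol(value):
    return np.asarray(value, dtype=float) / MGDL_PER_MMOL


def mmol_to_mgdl(value):
    return np.asarray(value, dtype=float) * MGDL_PER_MMOL


@dataclass
class GlucoseSeries:
    """One subject's timestamped glucose readings at a fixed sampling interval.

    Timestamps are strictly increasing; gaps are allowed but flagged when
    they are not an integer multiple of ``sampling_minutes``.
    """

    subject_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    sampling_minutes: int

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise GvarmError("timestamps and values differ in length")
        if len(self.timestamps) == 0:
            raise EmptyInputError("glucose series has no readings")
        diffs = np.diff(self.timestamps.asi8)
        if np.any(diffs <= 0):
            raise GvarmError("timestamps must be strictly increasing")
        if np.any(self.values <= 0):
            raise GvarmError("glucose values must be positive")
        step_ns = self.sampling_minutes * 60 * 1_000_000_000
        irregular = int(np.sum(diffs % step_ns != 0))
        if irregular:
            logger.warning(
                "%s: %d gaps are not multiples of the %d-min sampling interval",
                self.subject_id, irregular, self.sampling_minutes)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_gaps(self) -> int:
        """Number of missed sampling slots (gaps beyond one interval)."""
        step_ns = self.sampling_minutes * 60 * 1_000_000_000
        diffs = np.diff(self.timestamps.asi8)
        return int(np.sum(diffs // step_ns - 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "timestamp": self.timestamps,
            "glucose_mgdl": self.values,
        })

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps)


@dataclass(frozen=True)
class SleepEpisode:
    """One sleep bout with its onset and offset instants."""

    subject_id: str
    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self):
        if self.offset <= self.onset:
            raise GvarmError("sleep offset must be after onset")

    @property
    def duration(self) -> pd.Timedelta:
        return self.offset - self.onset


@dataclass
class DailySegments:
    """One day's in-sleep and awake glucose sub-series.

    ``day_index`` is the calendar date of the sleep offset. Each segment
    carries a ``complete`` flag: coverage (readings present over readings
    expected at the sampling interval) at least ``min_coverage``.
    """

    subject_id: str
    day_index: dt.date
    sleep: pd.Series
    awake: pd.Series
    sleep_complete: bool
    awake_complete: bool
    sleep_window: tuple = field(default=None)
    awake_window: tuple = field(default=None)


def _infer_sampling_minutes(timestamps: pd.DatetimeIndex) -> int:
    if len(timestamps) < 2:
        return 15
    diffs = pd.Series(np.diff(timestamps.asi8) // 60_000_000_000)
    return int(diffs.mode().iloc[0])


def _clean_cgm_frame(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    df["glucose_mgdl"] = pd.to_numeric(df["glucose_mgdl"], errors="coerce")
    bad = df["glucose_mgdl"].isna() | (df["glucose_mgdl"] <= 0)
    if bad.any():
        logger.warning("%s: dropped %d rows with non-numeric or non-positive "
                       "glucose", origin, int(bad.sum()))
        df = df[~bad]
    df = df.sort_values("timestamp", kind="stable")
    dup = df["timestamp"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: collapsed %d duplicate timestamps (first kept)",
                       origin, int(dup.sum()))
        df = df[~dup]
    return df


def read_cgm(path, subject_id: str | None = None,
             sampling_minutes: int | None = None) -> GlucoseSeries:
    """Read one subject's CGM CSV export.

    Multi-subject files require ``subject_id`` (or use
    :func:`read_cgm_cohort`). Rows with non-numeric glucose are dropped
    with a logged count, duplicate timestamps collapsed keeping the
    first.
    """
    df = pd.read_csv(path, dtype=str)
    if set(LIBRE_COLUMNS) <= set(df.columns):
        df = df.rename(columns=LIBRE_COLUMNS)
    missing = {"timestamp", "glucose_mgdl"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "subject_id" in df.columns:
        ids = df["subject_id"].unique()
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        elif len(ids) == 1:
            subject_id = str(ids[0])
        else:
            raise FormatError(
                f"{path}: {len(ids)} subjects present; pass subject_id= or "
                "use read_cgm_cohort")
    if subject_id is None:
        subject_id = str(path)
    df = _clean_cgm_frame(df, str(path))
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid glucose rows")
    ts = pd.DatetimeIndex(df["timestamp"])
    if sampling_minutes is None:
        sampling_minutes = _infer_sampling_minutes(ts)
    return GlucoseSeries(subject_id=str(subject_id), timestamps=ts,
                         values=df["glucose_mgdl"].to_numpy(dtype=float),
                         sampling_minutes=sampling_minutes)


def read_cgm_cohort(path) -> dict[str, GlucoseSeries]:
    """Read a multi-subject CGM CSV into a dict keyed by subject id."""
    df = pd.read_csv(path, dtype=str)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: multi-subject file needs a subject_id column")
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = _clean_cgm_frame(grp, f"{path}[{sid}]")
        if len(grp) == 0:
            logger.warning("%s: subject %s has no valid rows, skipped", path, sid)
            continue
        ts = pd.DatetimeIndex(grp["timestamp"])
        out[str(sid)] = GlucoseSeries(
            subject_id=str(sid), timestamps=ts,
            values=grp["glucose_mgdl"].to_numpy(dtype=float),
            sampling_minutes=_infer_sampling_minutes(ts))
    if not out:
        raise EmptyInputError(f"{path}: no valid glucose rows")
    return out


def write_cgm(series, path) -> None:
    """Write one series or a list of series in the native CSV dialect."""
    if isinstance(series, GlucoseSeries):
        series = [series]
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False)


def _merge_episodes(episodes: list[SleepEpisode], origin: str) -> list[SleepEpisode]:
    episodes = sorted(episodes, key=lambda e: e.onset)
    merged: list[SleepEpisode] = []
    for ep in episodes:
        if merged and ep.onset < merged[-1].offset:
            logger.warning("%s: merged overlapping sleep episodes", origin)
            last = merged.pop()
            merged.append(SleepEpisode(last.subject_id, last.onset,
                                       max(last.offset, ep.offset)))
        else:
            merged.append(ep)
    return merged


def read_sleep(path, subject_id: str | None = None) -> list[SleepEpisode]:
    """Read a sleep log; episodes sorted by onset, overlaps merged.

    Rows with ``offset <= onset`` are rejected with a logged count.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"onset", "offset"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "subject_id" in df.columns:
        ids = df["subject_id"].unique()
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        elif len(ids) == 1:
            subject_id = str(ids[0])
        else:
            raise FormatError(
                f"{path}: {len(ids)} subjects present; pass subject_id= or "
                "use read_sleep_cohort")
    if subject_id is None:
        subject_id = str(path)
    onset = pd.to_datetime(df["onset"], format="mixed")
    offset = pd.to_datetime(df["offset"], format="mixed")
    bad = offset <= onset
    if bad.any():
        logger.warning("%s: rejected %d rows with offset <= onset",
                       path, int(bad.sum()))
    episodes = [SleepEpisode(str(subject_id), on, off)
                for on, off, ok in zip(onset, offset, ~bad) if ok]
    return _merge_episodes(episodes, str(path))


def read_sleep_cohort(path) -> dict[str, list[SleepEpisode]]:
    df = pd.read_csv(path, dtype=str)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: multi-subject file needs a subject_id column")
    out: dict[str, list[SleepEpisode]] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        onset = pd.to_datetime(grp["onset"], format="mixed")
        offset = pd.to_datetime(grp["offset"], format="mixed")
        ok = offset > onset
        if (~ok).any():
            logger.warning("%s[%s]: rejected %d rows with offset <= onset",
                           path, sid, int((~ok).sum()))
        eps = [SleepEpisode(str(sid), on, off)
               for on, off, keep in zip(onset, offset, ok) if keep]
        out[str(sid)] = _merge_episodes(eps, f"{path}[{sid}]")
    return out


def write_sleep(episodes, path) -> None:
    """Write sleep episodes (one subject's list or a dict of lists)."""
    if isinstance(episodes, dict):
        flat = [e for eps in episodes.values() for e in eps]
    else:
        flat = list(episodes)
    frame = pd.DataFrame({
        "subject_id": [e.subject_id for e in flat],
        "onset": [e.onset.strftime("%Y-%m-%dT%H:%M:%S") for e in flat],
        "offset": [e.offset.strftime("%Y-%m-%dT%H:%M:%S") for e in flat],
    })
    frame.to_csv(path, index=False)


def _main_episode_per_day(episodes: list[SleepEpisode]) -> list[SleepEpisode]:
    """Keep the longest episode per offset date; naps fold into awake time."""
    by_day: dict[dt.date, SleepEpisode] = {}
    for ep in episodes:
        day = ep.offset.date()
        if day not in by_day or ep.duration > by_day[day].duration:
            by_day[day] = ep
    dropped = len(episodes) - len(by_day)
    if dropped:
        logger.info("dropped %d non-main sleep episodes (naps)", dropped)
    return [by_day[d] for d in sorted(by_day)]


def _coverage_complete(n_readings: int, window: tuple, sampling_minutes: int,
                       min_coverage: float) -> bool:
    start, end = window
    expected = int((end - start).total_seconds() // (sampling_minutes * 60))
    if expected <= 0:
        return False
    return n_readings / expected >= min_coverage


def segment_days(series: GlucoseSeries, episodes: list[SleepEpisode],
                 min_coverage: float = 0.7) -> list[DailySegments]:
    """Split a series into per-day sleep and awake segments.

    One :class:`DailySegments` is produced per main sleep episode, keyed
    by the calendar date of the episode's offset. The awake segment of a
    day runs from that day's sleep offset to the next day's sleep onset
    (so the last day has an empty, incomplete awake segment). Readings
    before the first sleep offset or after the last onset fall outside
    every window and are excluded.
    """
    if not episodes:
        logger.warning("%s: no sleep episodes, nothing to segment",
                       series.subject_id)
        return []
    if any(e.subject_id != series.subject_id for e in episodes):
        raise GvarmError("series and episodes belong to different subjects")
    eps = _main_episode_per_day(episodes)
    s = series.as_series()
    out = []
    for i, ep in enumerate(eps):
        sleep_win = (ep.onset, ep.offset)
        sleep_seg = s[(s.index >= ep.onset) & (s.index < ep.offset)]
        if i + 1 < len(eps):
            awake_win = (ep.offset, eps[i + 1].onset)
            awake_seg = s[(s.index >= ep.offset) & (s.index < eps[i + 1].onset)]
            awake_ok = _coverage_complete(len(awake_seg), awake_win,
                                          series.sampling_minutes, min_coverage)
        else:
            awake_win = (ep.offset, ep.offset)
            awake_seg = s.iloc[0:0]
            awake_ok = False
        out.append(DailySegments(
            subject_id=series.subject_id,
            day_index=ep.offset.date(),
            sleep=sleep_seg, awake=awake_seg,
            sleep_complete=_coverage_complete(len(sleep_seg), sleep_win,
                                              series.sampling_minutes,
                                              min_coverage),
            awake_complete=awake_ok,
            sleep_window=sleep_win, awake_window=awake_win,
        ))
    return out


def build_pairs(days: list[DailySegments]):
    """Build the two temporally ordered segment pairings.

    Type-1 pairs couple the awake segment of day N-1 with the sleep
    segment of day N (consecutive calendar dates only); type-2 pairs
    couple the sleep and awake segments of the same day N. Pairs
    containing an incomplete segment are dropped with a logged count.

    Returns ``(type1, type2)`` where type-1 entries are
    ``(prev_day, day)`` tuples of :class:`DailySegments` and type-2
    entries are single :class:`DailySegments`.
    """
    days = sorted(days, key=lambda d: d.day_index)
    type1, type2 = [], []
    dropped1 = dropped2 = 0
    by_date = {d.day_index: d for d in days}
    for d in days:
        prev = by_date.get(d.day_index - dt.timedelta(days=1))
        if prev is not None:
            if prev.awake_complete and d.sleep_complete:
                type1.append((prev, d))
            else:
                dropped1 += 1
        if d.sleep_complete and d.awake_complete:
            type2.append(d)
        else:
            dropped2 += 1
    if dropped1 or dropped2:
        logger.info("dropped %d type-1 and %d type-2 pairs with incomplete "
                    "segments", dropped1, dropped2)
    return type1, type2
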