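"""Localize event logs, segment them into participant-local days, and apply
the study's inclusion filters.

The raw log is a stream of time-stamped records per participant, written at
battery-change sampling events: screen on/off transitions, internet
connected/disconnected transitions, and foreground-app launches. This module

* converts UTC timestamps to each participant's local time zone,
* segments the stream into local calendar days and summarizes each day
  (hourly modal states, per-epoch and per-day event counts, state-duration
  minutes, app launch frequencies, first/last app-use minutes),
* counts *missing log intervals* per day (scheduled battery-change samples
  that produced no log), and
* applies the two inclusion filters: drop days with >= 10 missing log
  intervals, then keep only assessments backed by >= 8 retained days in
  their 14-day window.

State reconstruction uses carry-forward: between transition logs the state
stays constant; before a participant's first log the screen is "off" and the
internet "disconnected". An hour's modal state is the state occupying the
most minutes of that hour, ties broken toward off/disconnected.
"""

from __future__ import annotations

from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .features import EPOCH_EVENT_TYPES

__all__ = [
    "localize_and_segment",
    "filter_days",
    "filter_responses",
    "MAX_MISSING_INTERVALS",
    "MIN_DAYS_IN_WINDOW",
    "WINDOW_DAYS",
]

#: Days with at least this many missing log intervals are excluded.
MAX_MISSING_INTERVALS = 10
#: Assessments need at least this many retained days in their window.
MIN_DAYS_IN_WINDOW = 8
#: Length of the assessment window in calendar days (response day inclusive).
WINDOW_DAYS = 14

_ON_TOKENS = {"on", "connected"}


def _check_timezone(tz: str) -> ZoneInfo:
    try:
        return ZoneInfo(tz)
    except Exception as exc:  # KeyError or ZoneInfoNotFoundError
        raise ValueError(f"unknown timezone {tz!r}") from exc


def _to_local_naive(ts: pd.Series, tz: str) -> pd.Series:
    """UTC timestamps -> local wall-clock time (tz dropped after conversion)."""
    t = pd.to_datetime(ts, utc=True, format="ISO8601")
    return t.dt.tz_convert(_check_timezone(tz).key).dt.tz_localize(None)


def _hourly_on_minutes(
    trans_min: np.ndarray, trans_state: np.ndarray, date_offsets: np.ndarray
) -> np.ndarray:
    """Minutes spent in the "on" state for each hour of each requested day.

    Parameters
    ----------
    trans_min
        Sorted transition times in minutes since a participant reference.
    trans_state
        State (1 = on) in force from each transition until the next.
    date_offsets
        Start minute (since the same reference) of each local date 00:00.

    Returns
    -------
    ndarray of shape (n_dates, 24).
    """
    edges = (date_offsets[:, None] + 60.0 * np.arange(25)[None, :]).ravel()
    if trans_min.size == 0:
        return np.zeros((date_offsets.size, 24))
    # prefix "on"-duration function F(t), piecewise linear under carry-forward
    durations = np.diff(trans_min, append=max(edges.max(), trans_min[-1]))
    cum_on = np.concatenate([[0.0], np.cumsum(durations * trans_state)])
    idx = np.searchsorted(trans_min, edges, side="right") - 1
    inside = idx >= 0
    f = np.zeros_like(edges)
    f[inside] = cum_on[idx[inside]] + trans_state[idx[inside]] * (
        edges[inside] - trans_min[idx[inside]]
    )
    per_edge = f.reshape(date_offsets.size, 25)
    return np.diff(per_edge, axis=1)


def _summarize_participant(
    ev: pd.DataFrame, tz: str, sched: pd.DataFrame | None
) -> pd.DataFrame:
    """Build the per-day summary table for one participant's sorted events."""
    local = _to_local_naive(ev["timestamp_utc"], tz)
    dates = local.dt.normalize()
    observed = np.sort(dates.unique())
    ref = observed[0]
    minutes = (local - ref).dt.total_seconds().to_numpy() / 60.0
    date_offsets = (observed - ref) / np.timedelta64(1, "m")

    n_obs = observed.size
    cols: dict = {
        "participant_id": np.repeat(ev["participant_id"].iloc[0], n_obs),
        "local_date": pd.DatetimeIndex(observed).date,
    }

    hour = local.dt.hour.to_numpy()
    date_idx = np.searchsorted(date_offsets, minutes, side="right") - 1

    # hourly on-minutes, modal states, and day-level duration totals
    for stream, prefix, minutes_col in (
        ("screen", "screen", "screen_on_minutes"),
        ("internet", "net", "net_connected_minutes"),
    ):
        mask = (ev["stream"] == stream).to_numpy()
        st = ev.loc[mask, "value"].isin(_ON_TOKENS).to_numpy(dtype=float)
        on_min = _hourly_on_minutes(minutes[mask], st, date_offsets)
        modal = (on_min > 30.0).astype(int)  # ties (==30) resolve to off
        for h in range(24):
            cols[f"{prefix}_h{h}"] = modal[:, h]
        cols[minutes_col] = on_min.sum(axis=1)

    # event counts per epoch and per day
    etype = np.where(
        ev["stream"].to_numpy() == "app",
        "app_use",
        np.where(
            ev["stream"].to_numpy() == "screen",
            np.where(ev["value"].isin(_ON_TOKENS), "screen_on", "screen_off"),
            np.where(ev["value"].isin(_ON_TOKENS), "net_connected", "net_disconnected"),
        ),
    )
    counts = (
        pd.DataFrame({"d": date_idx, "e": hour // 6, "t": etype})
        .groupby(["d", "t", "e"])
        .size()
    )
    for t in EPOCH_EVENT_TYPES:
        for e in range(4):
            series = np.zeros(n_obs, dtype=int)
            try:
                sub = counts.xs((t, e), level=("t", "e"))
                series[sub.index.to_numpy()] = sub.to_numpy()
            except KeyError:
                pass
            cols[f"ep{e}_{t}"] = series
        cols[f"{t}_count"] = sum(cols[f"ep{e}_{t}"] for e in range(4))

    # app-level summaries
    app_mask = (ev["stream"] == "app").to_numpy()
    app = pd.DataFrame(
        {
            "d": date_idx[app_mask],
            "h": hour[app_mask],
            "app": ev.loc[app_mask, "value"].to_numpy(),
            "minute": minutes[app_mask] - date_offsets[date_idx[app_mask]],
        }
    )
    cols["app_distinct_count"] = np.zeros(n_obs, dtype=int)
    cols["first_app_minute"] = np.full(n_obs, np.nan)
    cols["last_app_minute"] = np.full(n_obs, np.nan)
    app_freqs = np.full(n_obs, "", dtype=object)
    for h in range(24):
        cols[f"appn_h{h}"] = np.zeros(n_obs, dtype=int)
    if len(app):
        per_hour = app.groupby(["d", "h"])["app"].nunique().unstack(fill_value=0)
        for h in per_hour.columns:
            cols[f"appn_h{h}"][per_hour.index.to_numpy()] = per_hour[h].to_numpy()
        grp = app.groupby("d")
        d_idx = grp.size().index.to_numpy()
        cols["app_distinct_count"][d_idx] = grp["app"].nunique().to_numpy()
        cols["first_app_minute"][d_idx] = np.floor(grp["minute"].min().to_numpy())
        cols["last_app_minute"][d_idx] = np.floor(grp["minute"].max().to_numpy())
        freqs = grp["app"].apply(
            lambda s: ";".join(f"{k}:{v}" for k, v in s.value_counts().items())
        )
        app_freqs[freqs.index.to_numpy()] = freqs.to_numpy()
    cols["app_freqs"] = app_freqs

    cols["missing_intervals"] = _missing_per_day(ev, tz, sched, observed, minutes, date_idx)
    return pd.DataFrame(cols)


def _missing_per_day(
    ev: pd.DataFrame,
    tz: str,
    sched: pd.DataFrame | None,
    observed: np.ndarray,
    minutes: np.ndarray,
    date_idx: np.ndarray,
) -> np.ndarray:
    """Missing log intervals per observed day.

    With a known sampling schedule the count is exact: scheduled
    battery-change events flagged as unlogged, attributed to local dates.
    Without one, a missing interval is inferred as a gap between consecutive
    logs exceeding twice the participant-day median gap.
    """
    n = observed.size
    if sched is not None and len(sched):
        s_local = _to_local_naive(sched["timestamp_utc"], tz)
        s_dates = s_local.dt.normalize().to_numpy()
        miss = sched["missing"].astype(bool).to_numpy()
        out = np.zeros(n, dtype=int)
        pos = np.searchsorted(observed, s_dates[miss])
        valid = (pos < n) & (observed[np.minimum(pos, n - 1)] == s_dates[miss])
        np.add.at(out, pos[valid], 1)
        return out
    out = np.zeros(n, dtype=int)
    for d in range(n):
        t = np.sort(minutes[date_idx == d])
        if t.size < 3:
            continue
        gaps = np.diff(t)
        med = np.median(gaps)
        if med > 0:
            out[d] = int(np.sum(gaps > 2.0 * med))
    return out


def localize_and_segment(
    events: pd.DataFrame,
    profiles: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convert UTC logs to local time and summarize each participant-day.

    Parameters
    ----------
    events
        Event log with columns ``participant_id``, ``timestamp_utc``
        (ISO-8601 or datetime), ``stream`` in {screen, internet, app},
        ``value``, ``battery_level``; sorted in time per participant.
    profiles
        Participant table carrying ``participant_id`` and ``timezone``
        (IANA zone name).
    schedule
        Optional battery-change sampling schedule (``participant_id``,
        ``timestamp_utc``, ``missing``) used for exact missing-interval
        counts; otherwise missing intervals are inferred from log gaps.

    Returns
    -------
    pandas.DataFrame
        One row per participant and local calendar date having at least one
        event, with hourly modal states, epoch/day counts, duration minutes,
        app summaries and ``missing_intervals``.
    """
    if len(events) == 0:
        return pd.DataFrame()
    tz_map = profiles.set_index("participant_id")["timezone"].to_dict()
    sched_groups = (
        dict(iter(schedule.groupby("participant_id", sort=False)))
        if schedule is not None
        else {}
    )
    pieces = []
    for pid, ev in events.groupby("participant_id", sort=False):
        if pid not in tz_map:
            raise ValueError(f"no profile (timezone) for participant {pid!r}")
        pieces.append(
            _summarize_participant(
                ev.reset_index(drop=True), tz_map[pid], sched_groups.get(pid)
            )
        )
    return pd.concat(pieces, ignore_index=True)


def filter_days(days: pd.DataFrame) -> pd.DataFrame:
    """Retain days with fewer than :data:`MAX_MISSING_INTERVALS` missing
    log intervals."""
    if len(days) == 0:
        return days
    return days.loc[days["missing_intervals"] < MAX_MISSING_INTERVALS].reset_index(
        drop=True
    )


def filter_responses(
    responses: pd.DataFrame,
    days: pd.DataFrame,
    *,
    window_days: int = WINDOW_DAYS,
    min_days: int = MIN_DAYS_IN_WINDOW,
    include_response_day: bool = True,
) -> pd.DataFrame:
    """Keep PHQ-8 responses backed by enough retained days of data.

    A response on date ``d`` is retained when its assessment window — the
    ``window_days`` calendar days ending on ``d`` (inclusive by default) —
    contains at least ``min_days`` retained days for that participant.
    """
    if len(responses) == 0:
        return responses.reset_index(drop=True)
    day_dates: dict = {}
    if len(days):
        for pid, grp in days.groupby("participant_id", sort=False):
            day_dates[pid] = np.sort(
                pd.to_datetime(grp["local_date"]).to_numpy(dtype="datetime64[D]")
            )
    keep = []
    resp_dates = pd.to_datetime(responses["response_date"]).dt.normalize()
    for (_, row), d in zip(responses.iterrows(), resp_dates):
        dates = day_dates.get(row["participant_id"])
        if dates is None:
            keep.append(False)
            continue
        end = np.datetime64(d, "D") + (0 if include_response_day else -1)
        start = end - (window_days - 1)
        n_in = int(
            np.searchsorted(dates, end, side="right")
            - np.searchsorted(dates, start, side="left")
        )
        keep.append(n_in >= min_days)
    return responses.loc[keep].reset_index(drop=True)
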