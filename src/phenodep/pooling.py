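"""Aggregate day-level markers into one analysis row per PHQ-8 response.

Each PHQ-8 assessment covers the preceding two weeks, so day-level features
are pooled over the 14 calendar days ending on the response date
(inclusive): count, entropy, regularity and app-use-time features by their
window mean (days with a missing value contribute nothing), and epoch-SD
features by the pooled SD

    s_pool = sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) )

with n_i = 4 epochs per day — i.e. the square root of the mean daily
variance. The binary outcome label is 1 iff the PHQ-8 total is >= 10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import CANONICAL_FEATURES
from .preprocess import MIN_DAYS_IN_WINDOW, WINDOW_DAYS

__all__ = ["SD_FEATURES", "pool_window", "pool_samples", "label_phq8", "deduplicate"]

#: Features pooled as SDs rather than means.
SD_FEATURES: tuple[str, ...] = (
    "screen_onCountSD",
    "screen_offCountSD",
    "net_connectedCountSD",
    "net_disconnectedCountSD",
    "app_countSD",
)


def label_phq8(total) -> int:
    """Binary depression label from a PHQ-8 total: 1 iff total >= 10."""
    t = float(total)
    if not 0 <= t <= 24:
        raise ValueError(f"PHQ-8 total must be in [0, 24], got {total!r}")
    return int(t >= 10)


def pooled_sd(daily_sds, n_per_day: int = 4) -> float:
    """Pooled SD across days from per-day sample SDs, each on ``n_per_day``
    epochs: sqrt of the df-weighted mean variance (equal df per day)."""
    s = np.asarray(daily_sds, dtype=float)
    s = s[~np.isnan(s)]
    if s.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(s**2)))


def pool_window(
    window_days: pd.DataFrame,
    response: pd.Series | dict,
    *,
    feature_names=CANONICAL_FEATURES,
    min_days: int = MIN_DAYS_IN_WINDOW,
) -> dict:
    """Pool one response's window of day features into a single sample row.

    ``window_days`` must already be restricted to the response's assessment
    window and contain at least ``min_days`` rows (the upstream response
    filter guarantees this).
    """
    if len(window_days) < min_days:
        raise ValueError(
            f"assessment window has {len(window_days)} days; expected >= {min_days}"
        )
    row = {
        "participant_id": response["participant_id"],
        "response_date": response["response_date"],
    }
    for feat in feature_names:
        vals = window_days[feat]
        if feat in SD_FEATURES:
            row[feat] = pooled_sd(vals)
        else:
            row[feat] = float(vals.mean(skipna=True))
    total = int(response["phq8_total"])
    row["phq8_total"] = total
    row["label"] = label_phq8(total)
    row["n_days_in_window"] = int(len(window_days))
    return row


def pool_samples(
    day_features: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    feature_names=CANONICAL_FEATURES,
    window_days: int = WINDOW_DAYS,
    include_response_day: bool = True,
    min_days: int = MIN_DAYS_IN_WINDOW,
) -> pd.DataFrame:
    """Build the pooled analysis table: one row per retained PHQ-8 response.

    Responses are expected to have passed the response filter; any response
    whose window holds fewer than ``min_days`` feature days raises.
    """
    rows = []
    by_pid = {
        pid: grp.assign(
            _date=pd.to_datetime(grp["local_date"]).to_numpy(dtype="datetime64[D]")
        )
        for pid, grp in day_features.groupby("participant_id", sort=False)
    }
    for _, resp in responses.iterrows():
        grp = by_pid.get(resp["participant_id"])
        if grp is None:
            raise ValueError(
                f"no feature days for participant {resp['participant_id']!r}"
            )
        end = np.datetime64(pd.Timestamp(resp["response_date"]).date(), "D")
        if not include_response_day:
            end -= 1
        start = end - (window_days - 1)
        in_win = grp.loc[(grp["_date"] >= start) & (grp["_date"] <= end)]
        rows.append(
            pool_window(in_win, resp, feature_names=feature_names, min_days=min_days)
        )
    return pd.DataFrame(rows)


def deduplicate(samples: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate rows over all feature columns plus the label,
    keeping first occurrences in order."""
    if len(samples) == 0:
        return samples.reset_index(drop=True)
    cols = [c for c in samples.columns if c in CANONICAL_FEATURES or c == "label"]
    return samples.drop_duplicates(subset=cols, keep="first").reset_index(drop=True)
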