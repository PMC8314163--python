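"""Day-level behavioral markers from smartphone event-log summaries.

The markers quantify how irregular, variable, and routine a participant's
phone use is within each local calendar day:

* **Counts** — how often each screen / internet state was entered and how
  many (distinct) foreground apps were launched.
* **Shannon entropy** (and its normalized form) of the day's state
  distribution: duration proportions for screen on/off and internet
  connected/disconnected, launch-frequency proportions per app.
* **Regularity index** — hour-by-hour similarity of today's behavior to the
  other days of the same ISO week, on values rescaled to [-0.5, 0.5].
* **Epoch SDs** — the sample SD of event counts across the four six-hour
  day epochs (night 0-5, morning 6-11, afternoon 12-17, evening 18-23).
* **App-use times** — minutes since local midnight of the first and last
  foreground-app launch.

The canonical day-level feature vector has exactly 22 entries
(:data:`CANONICAL_FEATURES`).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FEATURES",
    "shannon_entropy",
    "normalized_entropy",
    "regularity_index_pair",
    "rescale_binary_states",
    "rescale_count_pair",
    "daily_regularity",
    "epoch_count_sd",
    "extract_day_features",
]

#: The 22 canonical day-level markers: 6 counts, 6 entropies (raw +
#: normalized for screen, internet, app), 3 regularity indices, 5 epoch-count
#: SDs, and first/last app-use minutes.
CANONICAL_FEATURES: tuple[str, ...] = (
    "screen_onCount",
    "screen_offCount",
    "net_connectedCount",
    "net_disconnectedCount",
    "app_count",
    "app_distinctCount",
    "screen_entropy",
    "screen_normEntropy",
    "net_entropy",
    "net_normEntropy",
    "app_entropy",
    "app_normEntropy",
    "screen_regIndex",
    "net_regIndex",
    "app_regIndex",
    "screen_onCountSD",
    "screen_offCountSD",
    "net_connectedCountSD",
    "net_disconnectedCountSD",
    "app_countSD",
    "app_firstUseMinutes",
    "app_lastUseMinutes",
)

EPOCH_EVENT_TYPES = (
    "screen_on",
    "screen_off",
    "net_connected",
    "net_disconnected",
    "app_use",
)


def shannon_entropy(state_proportions) -> float:
    """Shannon entropy ``H = -sum p_i ln p_i`` in nats, with ``0 ln 0 := 0``.

    Parameters
    ----------
    state_proportions
        Non-negative proportions summing to 1 (within 1e-9).

    Raises
    ------
    ValueError
        If any proportion is negative or the vector does not sum to 1.
    """
    p = np.asarray(state_proportions, dtype=float)
    if p.ndim != 1:
        raise ValueError("state proportions must be a 1-D vector")
    if np.any(p < 0):
        raise ValueError("state proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"state proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_entropy(state_proportions) -> float:
    """Entropy divided by ``ln N`` (N = vector length), in [0, 1].

    A single-state vector (N = 1, or only one nonzero proportion with
    N taken as the vector length 1) returns 0 rather than 0/0.
    """
    p = np.asarray(state_proportions, dtype=float)
    n = p.size
    if n <= 1:
        # degenerate: one possible state carries no information
        if n == 1 and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("state proportions must sum to 1")
        return 0.0
    return shannon_entropy(p) / np.log(n)


def rescale_binary_states(states) -> np.ndarray:
    """Map hourly binary states (1 = on/connected, 0 = off/disconnected)
    to the regularity-index scale: 1 -> +0.5, 0 -> -0.5."""
    s = np.asarray(states, dtype=float)
    return s - 0.5


def rescale_count_pair(counts_a, counts_b) -> tuple[np.ndarray, np.ndarray]:
    """Rescale two days' hourly count vectors linearly to [-0.5, 0.5].

    The linear map is shared across the pair: ``[0, max(a, b)] -> [-0.5, 0.5]``
    so that the index is invariant to multiplying both days by a constant.
    A pair whose maximum is 0 is returned as all-zero vectors (the pair
    regularity is then defined as 0).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    m = max(a.max(initial=0.0), b.max(initial=0.0))
    if m <= 0:
        return np.zeros_like(a), np.zeros_like(b)
    return a / m - 0.5, b / m - 0.5


def regularity_index_pair(day_a, day_b) -> float:
    """Regularity index ``R(a, b) = (1/T) sum_t x_a(t) x_b(t)`` over T = 24
    hours, on hourly values already rescaled to [-0.5, 0.5].

    Bounded in [-0.25, 0.25]; +0.25 means identical saturated behavior at
    every hour, -0.25 perfectly opposite behavior.
    """
    a = np.asarray(day_a, dtype=float)
    b = np.asarray(day_b, dtype=float)
    if a.shape != (24,) or b.shape != (24,):
        raise ValueError("hourly vectors must have length 24")
    if np.any(np.abs(a) > 0.5 + 1e-9) or np.any(np.abs(b) > 0.5 + 1e-9):
        raise ValueError("hourly values must be rescaled to [-0.5, 0.5]")
    return float(a @ b) / 24.0


def daily_regularity(
    target_hourly, peer_hourly, *, kind: str = "binary"
) -> float:
    """Mean pairwise regularity of one day against its same-week peers.

    Parameters
    ----------
    target_hourly
        24-vector of the target day's hourly values (binary states or
        non-negative counts, per ``kind``).
    peer_hourly
        Iterable of peer days' 24-vectors from the same ISO week.
    kind
        ``"binary"`` rescales states to +/-0.5; ``"counts"`` rescales each
        pair linearly by the pair maximum.

    Returns
    -------
    float
        Mean pair regularity, or NaN when there are no peers.
    """
    peers = list(peer_hourly)
    if not peers:
        return float("nan")
    scores = []
    for peer in peers:
        if kind == "binary":
            a = rescale_binary_states(target_hourly)
            b = rescale_binary_states(peer)
        elif kind == "counts":
            a, b = rescale_count_pair(target_hourly, peer)
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown rescaler kind {kind!r}")
        scores.append(regularity_index_pair(a, b))
    return float(np.mean(scores))


def epoch_count_sd(epoch_counts) -> float:
    """Sample SD (ddof=1) of one event type's counts across the 4 epochs."""
    c = np.asarray(epoch_counts, dtype=float)
    if c.shape != (4,):
        raise ValueError("expected exactly 4 epoch counts")
    return float(np.std(c, ddof=1))


def _entropy_two_state(p_on: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-state entropy/normalized entropy from on-proportions."""
    p = np.clip(np.asarray(p_on, dtype=float), 0.0, 1.0)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    return h, h / np.log(2.0)


def _app_entropy_from_freqs(freq_str: str) -> tuple[float, float]:
    """Entropy of per-app launch frequencies serialized as ``id:count;...``."""
    if not isinstance(freq_str, str) or not freq_str:
        return float("nan"), float("nan")
    counts = np.array([float(tok.split(":")[1]) for tok in freq_str.split(";")])
    total = counts.sum()
    if total <= 0:
        return float("nan"), float("nan")
    p = counts / total
    h = shannon_entropy(p)
    n = p.size
    return h, (h / np.log(n) if n > 1 else 0.0)


def _week_regularity(days: pd.DataFrame, prefix: str, kind: str) -> pd.Series:
    """Per-day mean regularity against same-ISO-week peers, one participant-
    week group at a time."""
    hour_cols = [f"{prefix}_h{h}" for h in range(24)]
    out = pd.Series(np.nan, index=days.index, dtype=float)
    iso = pd.to_datetime(days["local_date"]).dt.isocalendar()
    group_key = [days["participant_id"], iso["year"], iso["week"]]
    for _, idx in days.groupby(group_key, sort=False).groups.items():
        if len(idx) < 2:
            continue
        mat = days.loc[idx, hour_cols].to_numpy(dtype=float)
        g = len(idx)
        if kind == "binary":
            x = mat - 0.5
            gram = (x @ x.T) / 24.0
            out.loc[idx] = (gram.sum(axis=1) - np.diag(gram)) / (g - 1)
        else:
            scores = np.zeros((g, g))
            for i, j in itertools.combinations(range(g), 2):
                a, b = rescale_count_pair(mat[i], mat[j])
                scores[i, j] = scores[j, i] = float(a @ b) / 24.0
            out.loc[idx] = scores.sum(axis=1) / (g - 1)
    return out


def extract_day_features(day_summaries: pd.DataFrame) -> pd.DataFrame:
    """Compute the 22 canonical markers for every participant-day.

    Parameters
    ----------
    day_summaries
        Day-summary table from :func:`phenodep.preprocess.localize_and_segment`
        (already passed through day filtering): one row per participant-day
        with hourly modal states, epoch counts, day counts, state-duration
        minutes, serialized app frequencies, and app-use times.

    Returns
    -------
    pandas.DataFrame
        One row per participant-day: ``participant_id``, ``local_date`` and
        the 22 :data:`CANONICAL_FEATURES` columns. Regularity indices are NaN
        for days with no same-week peer; app features are NaN on days with no
        app launches.
    """
    days = day_summaries.reset_index(drop=True)
    out = days[["participant_id", "local_date"]].copy()

    # counts straight from the day totals
    out["screen_onCount"] = days["screen_on_count"]
    out["screen_offCount"] = days["screen_off_count"]
    out["net_connectedCount"] = days["net_connected_count"]
    out["net_disconnectedCount"] = days["net_disconnected_count"]
    out["app_count"] = days["app_use_count"]
    out["app_distinctCount"] = days["app_distinct_count"]

    # entropy from state-duration proportions (screen / internet)
    h, hn = _entropy_two_state(days["screen_on_minutes"] / 1440.0)
    out["screen_entropy"], out["screen_normEntropy"] = h, hn
    h, hn = _entropy_two_state(days["net_connected_minutes"] / 1440.0)
    out["net_entropy"], out["net_normEntropy"] = h, hn

    # entropy from per-app launch frequencies
    app_h = days["app_freqs"].apply(_app_entropy_from_freqs)
    out["app_entropy"] = app_h.str[0]
    out["app_normEntropy"] = app_h.str[1]

    # regularity against the other retained days of the same ISO week
    out["screen_regIndex"] = _week_regularity(days, "screen", "binary")
    out["net_regIndex"] = _week_regularity(days, "net", "binary")
    out["app_regIndex"] = _week_regularity(days, "appn", "counts")

    # sample SD of counts across the 4 day epochs
    for etype, feat in (
        ("screen_on", "screen_onCountSD"),
        ("screen_off", "screen_offCountSD"),
        ("net_connected", "net_connectedCountSD"),
        ("net_disconnected", "net_disconnectedCountSD"),
        ("app_use", "app_countSD"),
    ):
        cols = [f"ep{e}_{etype}" for e in range(4)]
        out[feat] = days[cols].to_numpy(dtype=float).std(axis=1, ddof=1)

    out["app_firstUseMinutes"] = days["first_app_minute"]
    out["app_lastUseMinutes"] = days["last_app_minute"]
    return out
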