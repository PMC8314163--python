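"""Synthetic smartphone event logs and PHQ-8 responses.

The generator emulates a crowdsourced mobile-sensing study: Android
participants contribute screen on/off, internet connectivity, and
foreground-app launch logs, written opportunistically at ~1% battery-change
sampling events, alongside biweekly PHQ-8 depression self-reports.

Generative model
----------------
* **Population** — demographic categories drawn from the study's published
  marginals; one IANA time zone per participant, tied to country.
* **Observation span** — per-participant day counts drawn from the study's
  published day-distribution histogram (range 8-86, mean ~22).
* **Behavior** — screen and internet states follow two-state
  continuous-time Markov chains with participant-specific stationary
  probabilities and switching rates; app launches are a marked Poisson
  process on screen-on time with Zipf-weighted app choice.
* **Sampling** — a homogeneous Poisson battery-change schedule
  (~``battery_events_per_day`` events/day); each scheduled event either
  logs state changes and buffered app launches, or - with probability
  ``missing_interval_rate`` - goes missing (a "missing log interval").
* **Depression** — latent severity per 14-day window follows a
  participant random intercept plus AR(1) innovations (high intraclass
  correlation); PHQ-8 items come from a graded ordinal-logit response
  model calibrated so that ``P(total >= 10)`` equals the configured
  prevalence. Windows whose severity exceeds the matching quantile are
  "depressed": the screen chain's stationary probability is perturbed so
  the day's screen-state normalized entropy rises by ``entropy_effect``
  population SDs, and (optionally) the internet chain flips into an
  extreme-regularity or extreme-irregularity regime — a non-monotone
  signal invisible to linear statistics.

Everything is deterministic under ``seed``; each participant consumes an
independent child RNG stream derived from ``(seed, participant index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SynthConfig",
    "DEFAULT_ENTROPY_EFFECT",
    "TABLE_DEMOGRAPHIC_MARGINALS",
    "generate_population",
    "simulate_participant_days",
    "simulate_phq8",
    "generate_dataset",
    "entropy_effect_for_r",
]

#: Default standardized screen-entropy shift for depressed windows,
#: calibrated (via :func:`entropy_effect_for_r` at large pilot n) so the
#: pooled-sample Pearson correlation between screen-state normalized
#: entropy and the PHQ-8 total is ~0.14.
DEFAULT_ENTROPY_EFFECT = 0.54

# Published demographic marginals (counts out of 629, kept as exact fractions)
_N_REF = 629
TABLE_DEMOGRAPHIC_MARGINALS: dict[str, dict[str, float]] = {
    "age_group": {
        "18-24": 73 / _N_REF,
        "25-34": 204 / _N_REF,
        "35-44": 156 / _N_REF,
        "45-64": 166 / _N_REF,
        "65+": 30 / _N_REF,
    },
    "gender": {
        "female": 69 / _N_REF,
        "male": 546 / _N_REF,
        "other": 14 / _N_REF,
    },
    "education": {
        "elementary": 9 / _N_REF,
        "high_school": 98 / _N_REF,
        "none_or_undisclosed": 5 / _N_REF,
        "masters": 193 / _N_REF,
        "phd": 34 / _N_REF,
        "bachelors": 228 / _N_REF,
        "vocational": 62 / _N_REF,
    },
    "occupation": {
        "agriculture": 1 / _N_REF,
        "clerical": 14 / _N_REF,
        "craft_trade": 8 / _N_REF,
        "entrepreneur": 30 / _N_REF,
        "manager": 59 / _N_REF,
        "undisclosed": 34 / _N_REF,
        "professional": 227 / _N_REF,
        "retired": 39 / _N_REF,
        "sales_services": 29 / _N_REF,
        "home": 5 / _N_REF,
        "student": 74 / _N_REF,
        "technician": 90 / _N_REF,
        "unemployed": 19 / _N_REF,
    },
    "country": {
        "unknown": 91 / _N_REF,
        "US": 199 / _N_REF,
        "FI": 66 / _N_REF,
        "GB": 32 / _N_REF,
        "DE": 42 / _N_REF,
        "CA": 16 / _N_REF,
        "IN": 29 / _N_REF,
        "other": 154 / _N_REF,
    },
}

_COUNTRY_TZ = {
    "unknown": "UTC",
    "US": "America/New_York",
    "FI": "Europe/Helsinki",
    "GB": "Europe/London",
    "DE": "Europe/Berlin",
    "CA": "America/Toronto",
    "IN": "Asia/Kolkata",
}
_OTHER_TZ_POOL = (
    "Africa/Johannesburg",
    "America/Sao_Paulo",
    "Asia/Manila",
    "Asia/Tokyo",
    "Europe/Moscow",
    "Europe/Copenhagen",
    "Australia/Sydney",
    "Pacific/Auckland",
)

# Published per-participant day-count histogram: (lo, hi, probability)
_DAY_COUNT_BINS = (
    (8, 14, 0.579),
    (15, 28, 0.200),
    (29, 42, 0.084),
    (43, 56, 0.054),
    (57, 70, 0.046),
    (71, 84, 0.035),
    (85, 86, 0.002),
)

_STUDY_START = date(2018, 3, 1)
_START_SPREAD_DAYS = 120  # enrollment window within the Mar-Aug study period


@dataclass
class SynthConfig:
    """Configuration of the synthetic study.

    The headline fields (sample size, day range, sampling rate, prevalence,
    entropy effect, demographic marginals) mirror the emulated study; the
    behavior-process fields are free calibration constants with plausible
    defaults (the study reports no generative description of raw usage).
    """

    n_participants: int = 629
    days_range: tuple[int, int] = (8, 86)
    battery_events_per_day: float = 100.0
    missing_interval_rate: float = 0.03
    prevalence: float = 0.1681
    entropy_effect: float = DEFAULT_ENTROPY_EFFECT
    nonlinear_effect_flag: bool = False
    demographic_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in TABLE_DEMOGRAPHIC_MARGINALS.items()
        }
    )
    app_catalog_size: int = 50
    seed: int = 0

    # depression dynamics
    latent_icc: float = 0.7584
    ar1_phi: float = 0.5
    item_discrimination: float = 1.6
    item_offsets: tuple[float, float, float] = (0.0, 1.1, 2.2)

    # screen process: logit of stationary on-probability and cycles/day
    screen_logit_mean: float = -1.7
    screen_logit_sd: float = 0.7
    screen_day_sd: float = 0.3
    screen_cycles_mean: float = 40.0
    # internet process
    net_logit_mean: float = 1.6
    net_logit_sd: float = 0.8
    net_day_sd: float = 0.3
    net_cycles_mean: float = 8.0
    # app launches per screen-on minute (log-mean)
    app_rate_per_on_minute: float = 0.12

    def validate(self) -> None:
        for name in ("missing_interval_rate", "prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.days_range
        if lo < 8 or hi < lo:
            raise ValueError(f"days_range must satisfy 8 <= min <= max, got {self.days_range}")
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        for var, marg in self.demographic_marginals.items():
            probs = np.array(list(marg.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"marginal probabilities for {var!r} must be in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal for {var!r} must sum to 1 (got {probs.sum()!r})"
                )


# ---------------------------------------------------------------------------
# population


def generate_population(config: SynthConfig) -> pd.DataFrame:
    """Draw participant profiles from the configured demographic marginals.

    Returns a table with ``participant_id``, ``timezone`` and one column per
    demographic variable; deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_participants
    out = {"participant_id": [f"P{i:05d}" for i in range(n)]}
    for var, marg in config.demographic_marginals.items():
        cats = list(marg.keys())
        probs = np.array(list(marg.values()), dtype=float)
        probs = probs / probs.sum()  # exact renormalization of fp residue
        out[var] = rng.choice(cats, size=n, p=probs) if n else np.array([], dtype=object)
    df = pd.DataFrame(out)
    tzs = []
    for c in df.get("country", pd.Series(["unknown"] * n)):
        tzs.append(_COUNTRY_TZ.get(c, rng.choice(_OTHER_TZ_POOL)))
    df["timezone"] = tzs
    return df


# ---------------------------------------------------------------------------
# PHQ-8 graded response model


@lru_cache(maxsize=32)
def _phq_base_threshold(
    prevalence: float, a: float, offsets: tuple[float, float, float]
) -> float:
    """Base item threshold such that P(total >= 10) equals ``prevalence``
    when latent severity is standard normal (Gauss-Hermite + exact item
    convolution); solved by bisection."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    w = weights / weights.sum()

    def prev_at(base: float) -> float:
        b = base + np.asarray(offsets)
        ge = expit(a * (nodes[:, None] - b[None, :]))  # P(X >= 1..3 | s)
        pmf = np.stack(
            [1 - ge[:, 0], ge[:, 0] - ge[:, 1], ge[:, 1] - ge[:, 2], ge[:, 2]], axis=1
        )
        total = np.ones((len(nodes), 1))
        for _ in range(8):
            new = np.zeros((len(nodes), total.shape[1] + 3))
            for k in range(4):
                new[:, k : k + total.shape[1]] += total * pmf[:, k : k + 1]
            total = new
        return float(w @ total[:, 10:].sum(axis=1))

    lo, hi = -4.0, 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prev_at(mid) > prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phq8(
    severity, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw PHQ-8 item scores for each latent severity value.

    Returns an integer array of shape ``(len(severity), 8)`` with item
    scores in {0..3}; the row sum is the total score in [0, 24].
    """
    s = np.atleast_1d(np.asarray(severity, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("latent severity must be finite")
    base = _phq_base_threshold(
        config.prevalence, config.item_discrimination, tuple(config.item_offsets)
    )
    b = base + np.asarray(config.item_offsets)
    ge = expit(config.item_discrimination * (s[:, None, None] - b[None, None, :]))
    u = rng.random((s.size, 8, 1))
    return (u < ge).sum(axis=2).astype(int)


def _latent_severity(
    n_windows: int, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Participant-level random intercept + AR(1) window innovations;
    marginal N(0, 1) with intraclass correlation ``latent_icc``."""
    icc, phi = config.latent_icc, config.ar1_phi
    u = rng.normal(0.0, math.sqrt(icc))
    e = np.empty(n_windows)
    e[0] = rng.normal(0.0, math.sqrt(1.0 - icc))
    innov_sd = math.sqrt((1.0 - icc) * (1.0 - phi**2))
    for w in range(1, n_windows):
        e[w] = phi * e[w - 1] + rng.normal(0.0, innov_sd)
    return u + e


# ---------------------------------------------------------------------------
# entropy scale and inversion


def _h2_norm(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(p * np.log(p) + (1 - p) * np.log(1 - p)) / math.log(2.0)


@lru_cache(maxsize=32)
def _norm_entropy_ref_sd(mean: float, sd: float) -> float:
    """Population SD of the screen normalized entropy implied by the logit
    model, by Gauss-Hermite quadrature (reference scale for the injected
    standardized effect)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    w = weights / weights.sum()
    vals = _h2_norm(expit(mean + sd * nodes))
    m = float(w @ vals)
    return float(math.sqrt(max(w @ (vals - m) ** 2, 1e-12)))


def _invert_h2_norm(target: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Invert normalized two-state entropy: find p with H2n(p) = target on
    the lower (p <= .5) or upper branch, vectorized bisection."""
    t = np.clip(np.asarray(target, dtype=float), 0.0, 1.0)
    lo = np.full_like(t, 1e-9)
    hi = np.full_like(t, 0.5)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_low = _h2_norm(mid) < t
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    p = 0.5 * (lo + hi)
    return np.where(upper, 1.0 - p, p)


# ---------------------------------------------------------------------------
# event simulation


def _simulate_two_state_days(
    p_day: np.ndarray, cycles: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Alternating-exponential two-state chain for each day (1440 minutes).

    ``p_day`` is the stationary probability of state 1 and ``cycles`` the
    expected number of full on/off cycles; returns per-day transition
    minute arrays and the state entered at each transition (the day starts
    at minute 0 in a state drawn from the stationary law).
    """
    n_days = p_day.size
    kmax = int(np.ceil(4 * cycles.max() + 30))
    exp_draws = rng.exponential(size=(n_days, kmax))
    start_state = (rng.random(n_days) < p_day).astype(int)
    mean_on = p_day * 1440.0 / cycles
    mean_off = (1.0 - p_day) * 1440.0 / cycles
    parity = (np.arange(kmax)[None, :] + (start_state == 0)[:, None]) % 2
    # parity 0 -> currently in state 1 (duration mean_on), else state 0
    durations = np.where(parity == 0, mean_on[:, None], mean_off[:, None]) * exp_draws
    times = np.cumsum(durations, axis=1)
    trans_t, trans_s = [], []
    for d in range(n_days):
        valid = times[d] < 1440.0
        tt = times[d, valid]
        ss = (parity[d, valid] != 0).astype(int)  # state entered at transition
        trans_t.append(np.concatenate([[0.0], tt]))
        trans_s.append(np.concatenate([[start_state[d]], ss]))
    return trans_t, trans_s


def _day_depressed_mask(
    n_days: int, start: date, depressed_windows
) -> np.ndarray:
    mask = np.zeros(n_days, dtype=bool)
    for w_start, w_end in depressed_windows:
        lo = (w_start - start).days
        hi = (w_end - start).days
        lo, hi = max(lo, 0), min(hi, n_days - 1)
        if hi >= lo:
            mask[lo : hi + 1] = True
    return mask


def simulate_participant_days(
    profile,
    config: SynthConfig,
    depressed_windows=(),
    *,
    n_days: int | None = None,
    start_date: date | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one participant's event log and battery-change schedule.

    Parameters
    ----------
    profile
        Mapping/row with ``participant_id`` and ``timezone``.
    config
        Study configuration.
    depressed_windows
        Iterable of inclusive local-date ranges ``(start, end)`` during
        which the depressed-state perturbations apply.
    n_days, start_date, rng
        Observation span, first local date, and RNG stream; drawn from the
        configuration when omitted.

    Returns
    -------
    (events, schedule)
        Events: ``participant_id, timestamp_utc, stream, value,
        battery_level`` sorted by time, with screen/internet values strictly
        alternating per stream. Schedule: every scheduled battery sampling
        event with its ``missing`` flag.
    """
    config.validate()
    pid = profile["participant_id"]
    tz = profile["timezone"]
    if rng is None:
        rng = np.random.default_rng([config.seed, abs(hash(pid)) % (2**31)])
    if n_days is None:
        n_days = _draw_n_days(config, rng)
    if not config.days_range[0] <= n_days <= config.days_range[1]:
        raise ValueError(f"n_days {n_days} outside days_range {config.days_range}")
    if start_date is None:
        start_date = _STUDY_START + timedelta(int(rng.integers(0, _START_SPREAD_DAYS)))

    dep = _day_depressed_mask(n_days, start_date, depressed_windows)

    # participant-level behavior parameters
    z_s = rng.normal(config.screen_logit_mean, config.screen_logit_sd)
    c_s = rng.lognormal(math.log(config.screen_cycles_mean), 0.4)
    z_n = rng.normal(config.net_logit_mean, config.net_logit_sd)
    c_n = rng.lognormal(math.log(config.net_cycles_mean), 0.5)
    app_rate = rng.lognormal(math.log(config.app_rate_per_on_minute), 0.5)
    app_weights = 1.0 / np.arange(1, config.app_catalog_size + 1) ** 1.1
    app_weights /= app_weights.sum()
    app_ids = rng.permutation(config.app_catalog_size)

    # screen: per-day stationary probability, with the depressed-state
    # entropy shift applied on the normalized-entropy scale
    p_screen = expit(z_s + rng.normal(0.0, config.screen_day_sd, n_days))
    if config.entropy_effect != 0.0 and dep.any():
        sd_ref = _norm_entropy_ref_sd(
            config.screen_logit_mean,
            math.hypot(config.screen_logit_sd, config.screen_day_sd),
        )
        ne = _h2_norm(p_screen[dep])
        target = np.minimum(ne + config.entropy_effect * sd_ref, 0.999999)
        p_screen = p_screen.copy()
        p_screen[dep] = _invert_h2_norm(target, upper=p_screen[dep] > 0.5)
    cyc_s = np.full(n_days, c_s)

    # internet: optional non-monotone depressed-state regime switching
    p_net = expit(z_n + rng.normal(0.0, config.net_day_sd, n_days))
    cyc_n = np.full(n_days, c_n)
    if config.nonlinear_effect_flag:
        for w_start, w_end in depressed_windows:
            regular = rng.random() < 0.5
            lo = max((w_start - start_date).days, 0)
            hi = min((w_end - start_date).days, n_days - 1)
            if hi < lo:
                continue
            if regular:
                p_net[lo : hi + 1] = 0.98
                cyc_n[lo : hi + 1] = 2.0
            else:
                p_net[lo : hi + 1] = 0.5
                cyc_n[lo : hi + 1] = c_n * 4.0

    cyc_s = np.maximum(cyc_s, 1.0)
    cyc_n = np.maximum(cyc_n, 1.0)
    st_t, st_s = _simulate_two_state_days(p_screen, cyc_s, rng)
    nt_t, nt_s = _simulate_two_state_days(p_net, cyc_n, rng)

    day_offset = 1440.0 * np.arange(n_days)
    scr_times = np.concatenate([t + off for t, off in zip(st_t, day_offset)])
    scr_states = np.concatenate(st_s)
    net_times = np.concatenate([t + off for t, off in zip(nt_t, day_offset)])
    net_states = np.concatenate(nt_s)

    # app launches on screen-on intervals (marked Poisson, Zipf app choice)
    on_starts, on_ends = [], []
    for d in range(n_days):
        t, s = st_t[d], st_s[d]
        ends = np.append(t[1:], 1440.0)
        on = s == 1
        on_starts.append(t[on] + day_offset[d])
        on_ends.append(ends[on] + day_offset[d])
    on_starts = np.concatenate(on_starts)
    on_ends = np.concatenate(on_ends)
    on_durs = on_ends - on_starts
    total_on = on_durs.sum()
    n_apps = rng.poisson(app_rate * total_on) if total_on > 0 else 0
    if n_apps:
        u = np.sort(rng.uniform(0.0, total_on, n_apps))
        cum = np.concatenate([[0.0], np.cumsum(on_durs)])
        seg = np.searchsorted(cum, u, side="right") - 1
        app_times = on_starts[seg] + (u - cum[seg])
        app_choice = app_ids[rng.choice(config.app_catalog_size, n_apps, p=app_weights)]
    else:
        app_times = np.empty(0)
        app_choice = np.empty(0, dtype=int)

    # battery-change sampling schedule with missing intervals
    n_sched_per_day = rng.poisson(config.battery_events_per_day, n_days)
    sched_times = np.sort(
        np.repeat(day_offset, n_sched_per_day)
        + rng.uniform(0.0, 1440.0, int(n_sched_per_day.sum()))
    )
    missing = rng.random(sched_times.size) < config.missing_interval_rate
    battery = _battery_walk(sched_times.size, rng)

    logged = sched_times[~missing]
    log_batt = battery[~missing]

    def _log_changes(times, states):
        if logged.size == 0 or times.size == 0:
            return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
        idx = np.searchsorted(times, logged, side="right") - 1
        idx = np.maximum(idx, 0)
        st = states[idx]
        keep = np.concatenate([[True], st[1:] != st[:-1]])
        return logged[keep], st[keep], log_batt[keep]

    s_lt, s_ls, s_lb = _log_changes(scr_times, scr_states)
    n_lt, n_ls, n_lb = _log_changes(net_times, net_states)

    # app launches flush at the next non-missing sample; lost if that
    # sample is missing or never occurs
    if n_apps and sched_times.size:
        nxt = np.searchsorted(sched_times, app_times, side="left")
        ok = (nxt < sched_times.size) & ~missing[np.minimum(nxt, missing.size - 1)]
        app_times, app_choice = app_times[ok], app_choice[ok]
        app_batt = battery[np.minimum(nxt[ok], battery.size - 1)]
    else:
        app_times = np.empty(0)
        app_choice = np.empty(0, dtype=int)
        app_batt = np.empty(0, dtype=int)

    frames = [
        pd.DataFrame(
            {
                "minute": s_lt,
                "stream": "screen",
                "value": np.where(s_ls == 1, "on", "off"),
                "battery_level": s_lb,
            }
        ),
        pd.DataFrame(
            {
                "minute": n_lt,
                "stream": "internet",
                "value": np.where(n_ls == 1, "connected", "disconnected"),
                "battery_level": n_lb,
            }
        ),
        pd.DataFrame(
            {
                "minute": app_times,
                "stream": "app",
                "value": [f"app_{i:03d}" for i in app_choice],
                "battery_level": app_batt,
            }
        ),
    ]
    events = pd.concat(frames, ignore_index=True).sort_values(
        "minute", kind="stable", ignore_index=True
    )
    events.insert(0, "participant_id", pid)
    events["timestamp_utc"] = _minutes_to_utc(events.pop("minute"), start_date, tz)
    events = events[["participant_id", "timestamp_utc", "stream", "value", "battery_level"]]

    schedule = pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp_utc": _minutes_to_utc(pd.Series(sched_times), start_date, tz),
            "missing": missing,
        }
    )
    return events, schedule


def _battery_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """+/-1% battery levels folded into [5, 100] (each sample is one 1%
    battery change by construction)."""
    if n == 0:
        return np.empty(0, dtype=int)
    steps = rng.choice([-1, 1], size=n, p=[0.7, 0.3])
    walk = 60 + np.cumsum(steps)
    period = 2 * (100 - 5)
    folded = np.abs(((walk - 5) % period) - (period // 2))
    return (100 - folded).astype(int)


def _minutes_to_utc(minutes: pd.Series, start_date: date, tz: str) -> pd.Series:
    local = pd.Timestamp(start_date) + pd.to_timedelta(
        np.asarray(minutes, dtype=float), unit="m"
    )
    return (
        pd.DatetimeIndex(local)
        .tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
        .tz_convert("UTC")
        .to_series(index=minutes.index if hasattr(minutes, "index") else None)
        .reset_index(drop=True)
    )


def _draw_n_days(config: SynthConfig, rng: np.random.Generator) -> int:
    probs = np.array([b[2] for b in _DAY_COUNT_BINS])
    k = rng.choice(len(_DAY_COUNT_BINS), p=probs / probs.sum())
    lo, hi, _ = _DAY_COUNT_BINS[k]
    n = int(rng.integers(lo, hi + 1))
    return int(np.clip(n, config.days_range[0], config.days_range[1]))


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Generate the full study: profiles, event logs, sampling schedule,
    PHQ-8 responses, and the latent window table.

    Returns
    -------
    dict with keys ``profiles``, ``events``, ``schedule``, ``responses``
    (one row per PHQ-8 assessment: items, total, response date) and
    ``windows`` (latent severity and depressed flag per 14-day window).
    """
    config.validate()
    profiles = generate_population(config)
    dep_threshold = norm.ppf(1.0 - config.prevalence)

    ev_frames, sched_frames, resp_rows, win_rows = [], [], [], []
    for i, profile in profiles.iterrows():
        rng_lat = np.random.default_rng([config.seed, i, 0])
        rng_ev = np.random.default_rng([config.seed, i, 1])
        rng_phq = np.random.default_rng([config.seed, i, 2])

        n_days = _draw_n_days(config, rng_lat)
        start = _STUDY_START + timedelta(int(rng_lat.integers(0, _START_SPREAD_DAYS)))
        n_windows = (n_days - 1) // 14 + 1
        sev = _latent_severity(n_windows, config, rng_lat)
        depressed = sev > dep_threshold

        windows = []
        for w in range(n_windows):
            w_start = start + timedelta(14 * w)
            w_end = start + timedelta(14 * w + 13)
            windows.append((w_start, w_end))
            win_rows.append(
                {
                    "participant_id": profile["participant_id"],
                    "window": w,
                    "window_start": w_start,
                    "window_end": w_end,
                    "response_date": w_end,
                    "severity": sev[w],
                    "depressed": bool(depressed[w]),
                }
            )
        dep_windows = [win for win, d in zip(windows, depressed) if d]

        events, schedule = simulate_participant_days(
            profile,
            config,
            dep_windows,
            n_days=n_days,
            start_date=start,
            rng=rng_ev,
        )
        ev_frames.append(events)
        sched_frames.append(schedule)

        items = simulate_phq8(sev, config, rng_phq)
        for w in range(n_windows):
            row = {
                "participant_id": profile["participant_id"],
                "response_date": windows[w][1],
            }
            row.update({f"item_{j + 1}": int(items[w, j]) for j in range(8)})
            row["phq8_total"] = int(items[w].sum())
            resp_rows.append(row)

    events = (
        pd.concat(ev_frames, ignore_index=True)
        if ev_frames
        else pd.DataFrame(
            columns=["participant_id", "timestamp_utc", "stream", "value", "battery_level"]
        )
    )
    schedule = (
        pd.concat(sched_frames, ignore_index=True)
        if sched_frames
        else pd.DataFrame(columns=["participant_id", "timestamp_utc", "missing"])
    )
    return {
        "profiles": profiles,
        "events": events,
        "schedule": schedule,
        "responses": pd.DataFrame(
            resp_rows,
            columns=["participant_id", "response_date"]
            + [f"item_{j}" for j in range(1, 9)]
            + ["phq8_total"],
        ),
        "windows": pd.DataFrame(win_rows),
    }


def entropy_effect_for_r(
    target_r: float,
    config: SynthConfig | None = None,
    *,
    pilot_participants: int = 400,
    probe_effect: float = 0.4,
    seed: int = 12345,
) -> float:
    """Calibrate ``entropy_effect`` so the pooled-sample Pearson correlation
    between screen normalized entropy and the PHQ-8 total hits ``target_r``.

    Runs the full pipeline once on a pilot study at ``probe_effect`` and
    scales linearly (the correlation is linear in the injected shift for
    small effects). Deterministic under ``seed``.
    """
    from . import pooling, preprocess
    from .features import extract_day_features

    base = config or SynthConfig()
    pilot = replace(
        base, n_participants=pilot_participants, entropy_effect=probe_effect, seed=seed
    )
    data = generate_dataset(pilot)
    days = preprocess.filter_days(
        preprocess.localize_and_segment(data["events"], data["profiles"], data["schedule"])
    )
    responses = preprocess.filter_responses(data["responses"], days)
    feats = extract_day_features(days)
    pooled = pooling.pool_samples(feats, responses)
    r_probe = pooled["screen_normEntropy"].corr(pooled["phq8_total"])
    if not np.isfinite(r_probe) or abs(r_probe) < 1e-6:
        raise RuntimeError("pilot correlation degenerate; increase pilot size")
    return float(probe_effect * target_r / r_probe)
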