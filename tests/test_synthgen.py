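"""Synthetic study generator: determinism, marginals, invariants, effects."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from phenodep import preprocess
from phenodep.features import extract_day_features
from phenodep.synthgen import (
    SynthConfig,
    generate_dataset,
    generate_population,
    simulate_participant_days,
    simulate_phq8,
)


class TestGeneratePopulation:
    def test_empty_population(self):
        assert len(generate_population(SynthConfig(n_participants=0))) == 0

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(n_participants=200, seed=42)
        pd.testing.assert_frame_equal(
            generate_population(cfg), generate_population(cfg)
        )

    def test_marginals_converge(self):
        profiles = generate_population(SynthConfig(n_participants=4000, seed=5))
        male = (profiles["gender"] == "male").mean()
        p = 546 / 629
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs(male - p) < 3 * se

    def test_invalid_marginal_rejected(self):
        cfg = SynthConfig(n_participants=5)
        cfg.demographic_marginals["gender"] = {"female": 0.5, "male": 0.4}
        with pytest.raises(ValueError, match="sum to 1"):
            generate_population(cfg)

    def test_timezones_are_valid(self):
        from zoneinfo import ZoneInfo

        profiles = generate_population(SynthConfig(n_participants=100, seed=1))
        for tz in profiles["timezone"].unique():
            ZoneInfo(tz)


class TestSimulatePhq8:
    def test_items_in_range_and_total_consistent(self):
        rng = np.random.default_rng(0)
        items = simulate_phq8(rng.normal(size=500), SynthConfig(), rng)
        assert items.min() >= 0 and items.max() <= 3
        assert items.shape == (500, 8)
        totals = items.sum(axis=1)
        assert totals.min() >= 0 and totals.max() <= 24

    def test_extreme_severity_saturates_items(self):
        rng = np.random.default_rng(0)
        assert simulate_phq8([12.0], SynthConfig(), rng).sum() == 24
        assert simulate_phq8([-12.0], SynthConfig(), rng).sum() == 0

    def test_prevalence_calibration(self):
        cfg = SynthConfig()
        rng = np.random.default_rng(7)
        totals = simulate_phq8(rng.normal(size=10000), cfg, rng).sum(axis=1)
        frac = (totals >= 10).mean()
        se = np.sqrt(cfg.prevalence * (1 - cfg.prevalence) / 10000)
        assert abs(frac - cfg.prevalence) < 3 * se

    def test_nonfinite_severity_rejected(self):
        with pytest.raises(ValueError):
            simulate_phq8([np.nan], SynthConfig(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def participant():
    cfg = SynthConfig(seed=11)
    profile = {"participant_id": "P1", "timezone": "Europe/Helsinki"}
    rng = np.random.default_rng(11)
    events, schedule = simulate_participant_days(
        profile, cfg, n_days=15, start_date=date(2018, 4, 2), rng=rng
    )
    return events, schedule


class TestEventStreams:

    def test_timestamps_nondecreasing(self, participant):
        events, _ = participant
        ts = pd.to_datetime(events["timestamp_utc"])
        assert ts.is_monotonic_increasing

    def test_states_alternate_per_stream(self, participant):
        events, _ = participant
        for stream in ("screen", "internet"):
            vals = events.loc[events["stream"] == stream, "value"].to_numpy()
            assert all(a != b for a, b in zip(vals, vals[1:]))

    def test_battery_levels_in_range(self, participant):
        events, _ = participant
        assert events["battery_level"].between(0, 100).all()

    def test_no_missing_intervals_when_rate_zero(self):
        cfg = SynthConfig(missing_interval_rate=0.0, seed=2)
        profile = {"participant_id": "P1", "timezone": "UTC"}
        _, schedule = simulate_participant_days(
            profile, cfg, n_days=10, start_date=date(2018, 4, 2), rng=np.random.default_rng(2)
        )
        assert not schedule["missing"].any()

    def test_day_span_respects_range(self):
        cfg = SynthConfig(seed=3)
        with pytest.raises(ValueError, match="days_range"):
            simulate_participant_days(
                {"participant_id": "P1", "timezone": "UTC"},
                cfg,
                n_days=5,
                start_date=date(2018, 4, 2),
                rng=np.random.default_rng(0),
            )


class TestEffectInjection:
    def test_measured_entropy_shift_monotone_in_effect(self):
        """Paired comparison over an effect grid: identical RNG streams,
        so the measured screen-entropy mean must increase with the
        injected effect size."""
        start = date(2018, 4, 2)
        win = [(start, start + timedelta(200))]
        profile = {"participant_id": "X", "timezone": "UTC"}
        prof_df = pd.DataFrame([profile])
        means = {}
        for effect in (0.0, 0.4, 0.8):
            cfg = SynthConfig(entropy_effect=effect)
            vals = []
            for i in range(12):
                rng = np.random.default_rng([9, i])
                events, schedule = simulate_participant_days(
                    profile, cfg, win if effect else [], n_days=14,
                    start_date=start, rng=rng,
                )
                days = preprocess.filter_days(
                    preprocess.localize_and_segment(events, prof_df, schedule)
                )
                vals.append(extract_day_features(days)["screen_normEntropy"].mean())
            means[effect] = np.mean(vals)
        assert means[0.4] > means[0.0]
        assert means[0.8] > means[0.4]
        assert means[0.8] > means[0.0] + 0.05

    def test_zero_effect_windows_exchangeable(self):
        """With no injected effect the depressed flag carries no feature
        information: group means agree within Monte-Carlo error."""
        cfg = SynthConfig(n_participants=60, seed=13, entropy_effect=0.0)
        d = generate_dataset(cfg)
        days = preprocess.filter_days(
            preprocess.localize_and_segment(d["events"], d["profiles"], d["schedule"])
        )
        feats = extract_day_features(days)
        w = d["windows"]
        feats = feats.copy()
        feats["local_date"] = pd.to_datetime(feats["local_date"])
        dep_days = []
        for _, r in w.iterrows():
            if r["depressed"]:
                dep_days.append((r["participant_id"], r["window_start"], r["window_end"]))
        flag = np.zeros(len(feats), dtype=bool)
        for pid, lo, hi in dep_days:
            flag |= (
                (feats["participant_id"] == pid)
                & (feats["local_date"] >= pd.Timestamp(lo))
                & (feats["local_date"] <= pd.Timestamp(hi))
            ).to_numpy()
        g1 = feats.loc[flag, "screen_normEntropy"].dropna()
        g0 = feats.loc[~flag, "screen_normEntropy"].dropna()
        # crude SE accounting for clustering: participant-level spread
        se = feats.groupby("participant_id")["screen_normEntropy"].mean().std() * np.sqrt(
            1 / max(flag.sum() / 10, 1) + 1 / 50
        )
        assert abs(g1.mean() - g0.mean()) < 3 * se


class TestDatasetDeterminism:
    def test_identical_serialized_output(self):
        cfg = SynthConfig(n_participants=6, seed=99)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for key in a:
            assert a[key].to_csv(index=False) == b[key].to_csv(index=False)

    def test_responses_every_14_days(self, small_dataset):
        resp = small_dataset["responses"]
        for _, grp in resp.groupby("participant_id"):
            dates = pd.to_datetime(grp["response_date"]).sort_values()
            gaps = dates.diff().dropna().dt.days
            assert (gaps == 14).all()

    def test_day_counts_within_range(self, small_dataset):
        ev = small_dataset["events"].copy()
        spans = (
            pd.to_datetime(ev["timestamp_utc"], format="ISO8601", utc=True)
            .groupby(ev["participant_id"])
            .agg(lambda s: (s.max() - s.min()).days + 1)
        )
        assert spans.between(8, 88).all()  # tz shifts can add a boundary day
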