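"""Day-level marker computations against hand and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodep.features import (
    CANONICAL_FEATURES,
    daily_regularity,
    epoch_count_sd,
    extract_day_features,
    normalized_entropy,
    regularity_index_pair,
    rescale_binary_states,
    rescale_count_pair,
    shannon_entropy,
)
from tests.conftest import make_day_summary


def brute_entropy(p):
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0], 0.0),
            ([0.5, 0.5], math.log(2)),
            ([0.25, 0.75], 0.5623351446188083),
        ],
    )
    def test_known_values(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1, 1.1], [0.5, 0.4], [0.7, 0.7]])
    def test_invalid_proportions_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_entropy(bad)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(rng.integers(1, 8)))
            assert shannon_entropy(p) == pytest.approx(brute_entropy(p), abs=1e-12)


class TestNormalizedEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0, 0.0], 0.0),
            ([0.25, 0.75], 0.8112781244591328),
        ],
    )
    def test_known_values(self, p, expected):
        assert normalized_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_single_state_defined_as_zero(self):
        assert normalized_entropy([1.0]) == 0.0

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.dirichlet(np.ones(rng.integers(2, 10)))
            assert 0.0 <= normalized_entropy(p) <= 1.0 + 1e-12


class TestRegularityIndex:
    def test_extremes(self):
        same = np.full(24, 0.5)
        assert regularity_index_pair(same, same) == pytest.approx(0.25)
        assert regularity_index_pair(same, -same) == pytest.approx(-0.25)

    def test_half_opposed_vs_uniform_day_cancels(self):
        a = np.concatenate([np.full(12, 0.5), np.full(12, -0.5)])
        b = np.full(24, 0.5)
        assert regularity_index_pair(a, b) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_bounds_and_hour_permutation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-0.5, 0.5, 24)
        b = rng.uniform(-0.5, 0.5, 24)
        r = regularity_index_pair(a, b)
        assert r == pytest.approx(regularity_index_pair(b, a), abs=1e-12)
        assert -0.25 - 1e-12 <= r <= 0.25 + 1e-12
        perm = rng.permutation(24)
        assert regularity_index_pair(a[perm], b[perm]) == pytest.approx(r, abs=1e-12)

    def test_count_rescaling_invariant_to_common_scale(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 10, 24).astype(float)
        b = rng.integers(0, 10, 24).astype(float)
        ra = regularity_index_pair(*rescale_count_pair(a, b))
        rb = regularity_index_pair(*rescale_count_pair(3.7 * a, 3.7 * b))
        assert ra == pytest.approx(rb, abs=1e-12)

    def test_zero_count_pair_defined_as_zero(self):
        z = np.zeros(24)
        assert regularity_index_pair(*rescale_count_pair(z, z)) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            regularity_index_pair(np.zeros(23), np.zeros(23))


class TestDailyRegularity:
    def test_identical_binary_week_is_maximal(self):
        day = np.tile([1, 0], 12)
        assert daily_regularity(day, [day, day, day]) == pytest.approx(0.25)

    def test_no_peers_gives_missing(self):
        assert math.isnan(daily_regularity(np.zeros(24), []))

    def test_mean_of_pair_scores(self):
        target = np.ones(24)
        peers = [np.ones(24), np.concatenate([np.ones(12), np.zeros(12)]), np.zeros(24)]
        # pair scores: 0.25, 0.0, -0.25
        assert daily_regularity(target, peers) == pytest.approx(0.0, abs=1e-12)

    def test_binary_rescaler(self):
        np.testing.assert_allclose(
            rescale_binary_states([1, 0, 1]), [0.5, -0.5, 0.5]
        )


class TestEpochCountSD:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5, 5, 5), 0.0),
            ((0, 0, 0, 12), 6.0),
            ((1, 2, 3, 4), 1.2909944487358056),
        ],
    )
    def test_known_values(self, counts, expected):
        assert epoch_count_sd(counts) == pytest.approx(expected, abs=1e-12)

    def test_requires_exactly_four_epochs(self):
        with pytest.raises(ValueError):
            epoch_count_sd([1, 2, 3])


class TestExtractDayFeatures:
    def test_canonical_feature_count_is_22(self):
        assert len(CANONICAL_FEATURES) == 22

    def test_balanced_screen_day_has_unit_normalized_entropy(self):
        days = pd.DataFrame([make_day_summary(screen_on_minutes=720.0)])
        feats = extract_day_features(days)
        assert feats.loc[0, "screen_normEntropy"] == pytest.approx(1.0)
        assert feats.loc[0, "screen_entropy"] == pytest.approx(math.log(2))

    def test_single_app_day_has_zero_app_entropy(self):
        days = pd.DataFrame(
            [
                make_day_summary(
                    app_freqs="app_001:4",
                    app_distinct_count=1,
                    app_use_count=4,
                    first_app_minute=450.0,
                    last_app_minute=1335.0,
                )
            ]
        )
        feats = extract_day_features(days)
        assert feats.loc[0, "app_entropy"] == pytest.approx(0.0)
        assert feats.loc[0, "app_distinctCount"] == 1
        assert feats.loc[0, "app_firstUseMinutes"] == 450
        assert feats.loc[0, "app_lastUseMinutes"] == 1335

    def test_every_row_carries_exactly_22_feature_columns(self, small_features):
        feature_cols = [c for c in small_features.columns if c in CANONICAL_FEATURES]
        assert len(feature_cols) == 22
        assert set(small_features.columns) == {"participant_id", "local_date", *CANONICAL_FEATURES}

    def test_feature_ranges(self, small_features):
        f = small_features
        assert (f["screen_entropy"].dropna() >= 0).all()
        for c in ("screen_normEntropy", "net_normEntropy", "app_normEntropy"):
            col = f[c].dropna()
            assert ((col >= 0) & (col <= 1 + 1e-12)).all()
        for c in ("screen_regIndex", "net_regIndex", "app_regIndex"):
            col = f[c].dropna()
            assert ((col >= -0.25 - 1e-9) & (col <= 0.25 + 1e-9)).all()
        sd_cols = [c for c in CANONICAL_FEATURES if c.endswith("SD")]
        assert (f[sd_cols].dropna() >= 0).all().all()
        ok = f[["app_firstUseMinutes", "app_lastUseMinutes"]].dropna()
        assert (ok["app_firstUseMinutes"] <= ok["app_lastUseMinutes"]).all()
        assert (ok["app_lastUseMinutes"] <= 1439).all()
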