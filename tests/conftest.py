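import numpy as np
import pandas as pd
import pytest

from phenodep import pooling, preprocess
from phenodep.features import extract_day_features
from phenodep.synthgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic study shared across tests."""
    return generate_dataset(SynthConfig(n_participants=40, seed=3))


@pytest.fixture(scope="session")
def small_days(small_dataset):
    d = small_dataset
    return preprocess.filter_days(
        preprocess.localize_and_segment(d["events"], d["profiles"], d["schedule"])
    )


@pytest.fixture(scope="session")
def small_features(small_days):
    return extract_day_features(small_days)


@pytest.fixture(scope="session")
def small_pooled(small_dataset, small_days, small_features):
    responses = preprocess.filter_responses(small_dataset["responses"], small_days)
    pooled = pooling.deduplicate(pooling.pool_samples(small_features, responses))
    filled = pooled.copy()
    for c in filled.columns:
        if filled[c].dtype.kind == "f" and filled[c].isna().any():
            filled[c] = filled[c].fillna(filled[c].median())
    return filled


def make_day_summary(**overrides):
    """A minimal, fully populated single-day summary row for feature tests."""
    row = {"participant_id": "P1", "local_date": "2018-04-02"}
    for h in range(24):
        row[f"screen_h{h}"] = 0
        row[f"net_h{h}"] = 1
        row[f"appn_h{h}"] = 0
    for t in ("screen_on", "screen_off", "net_connected", "net_disconnected", "app_use"):
        for e in range(4):
            row[f"ep{e}_{t}"] = 0
        row[f"{t}_count"] = 0
    row.update(
        {
            "screen_on_minutes": 720.0,
            "net_connected_minutes": 1440.0,
            "app_distinct_count": 0,
            "first_app_minute": np.nan,
            "last_app_minute": np.nan,
            "app_freqs": "",
            "missing_intervals": 0,
        }
    )
    row.update(overrides)
    return row


@pytest.fixture
def day_summary_factory():
    return make_day_summary


def as_days_frame(rows):
    return pd.DataFrame(rows)
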