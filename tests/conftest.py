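import numpy as np
import pandas as pd
import pytest

import phenolag as pl


def make_series(temps, label="series", start_day=1):
    temps = np.asarray(temps, dtype=float)
    days = np.arange(start_day, start_day + len(temps))
    return pl.TemperatureSeries(days, temps, label=label)


def constant_series(value, n_days=365, label="series"):
    return make_series(np.full(n_days, float(value)), label=label)


def random_series_pair(rng, n_days=365, low=-20.0, high=30.0):
    """An arbitrary baseline/warmer pair; 'warmer' need not be warmer."""
    baseline = make_series(rng.uniform(low, high, n_days), "baseline")
    warmer = make_series(rng.uniform(low, high, n_days), "warmer")
    return baseline, warmer


@pytest.fixture(scope="session")
def study_partition():
    """A 200-record synthetic study (lags 0/2/5/10) with its partition table."""
    blocks = pl.study_config(200, lags=(0.0, 2.0, 5.0, 10.0))
    records, store = pl.generate_dataset(blocks, seed=123)
    table = pl.partition_table(records, store)
    return records, store, table
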