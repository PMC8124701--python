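import numpy as np
import pandas as pd
import pytest

from seasonalcgm.data import EventLog, GlucoseSeries
from seasonalcgm.partition import RegularizedPartition


@pytest.fixture
def simple_series():
    """One day of synthetic CGM on the 5-min grid, no blanks."""
    rng = np.random.default_rng(7)
    t = np.arange(288)
    values = 120 + 25 * np.sin(2 * np.pi * t / 288) + rng.normal(0, 2, 288)
    return GlucoseSeries(pd.Timestamp("2021-03-01"), values)


@pytest.fixture
def three_event_log():
    base = pd.Timestamp("2021-03-01")
    times = [base + pd.Timedelta(minutes=5 * off) for off in (0, 84, 200)]
    return EventLog(times, ["Breakfast", "Lunch", "Night"])


def planted_partition(n_per=20, L=40, noise_sd=5.0, seed=0, key="M", pr=5):
    """Three well-separated glucose templates with variable lengths/blanks."""
    rng = np.random.default_rng(seed)
    t = np.arange(L, dtype=float)
    templates = [
        140 + 80 * np.exp(-((t - 10) / 8.0) ** 2),
        100 + 4.0 * np.minimum(t, L - t),
        90 + 0.0 * t,
    ]
    rows, labels = [], []
    for j in range(3 * n_per):
        k = j % 3
        li = int(rng.integers(int(0.6 * L), L + 1))
        row = np.full(L, np.nan)
        row[:li] = templates[k][:li] + rng.normal(0, noise_sd, li)
        rows.append(row)
        labels.append(k)
    rows = np.array(rows)
    part = RegularizedPartition(
        key=key, L=L, Pr=pr,
        rows=rows,
        presamples=np.full((rows.shape[0], pr), 100.0),
        event_indices=list(range(rows.shape[0])),
        lengths=[int(np.sum(~np.isnan(r))) for r in rows],
    )
    return part, np.array(labels)


@pytest.fixture
def planted3():
    return planted_partition()
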