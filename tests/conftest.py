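import datetime as dt

import pytest

from pollenhq import (
    DailySample,
    PesticidePanel,
    PesticideProperty,
    ResidueSeries,
)

D0 = dt.date(2018, 4, 12)


def make_series(rows, panel, missing_days=()):
    """Build a series from {day_index: {analyte: conc}} with consecutive dates."""
    samples = [
        DailySample(d, D0 + dt.timedelta(days=d - 1), dict(conc))
        for d, conc in sorted(rows.items())
    ]
    return ResidueSeries(samples, panel, missing_days)


@pytest.fixture
def small_panel():
    return PesticidePanel([
        PesticideProperty("alpha", "fungicide", group="triazoles",
                          loq=3.0, recovery_pct=100, ld50_oral=100.0),
        PesticideProperty("beta", "insecticide", group="carbamates",
                          loq=3.0, recovery_pct=44, ld50_oral=0.5),
        PesticideProperty("gamma", "herbicide", group="dinitroanilines",
                          loq=5.0, recovery_pct=4, ld50_oral=50.0),
        PesticideProperty("delta", "insecticide", group="repellents",
                          loq=3.0, recovery_pct=None, ld50_oral=None),
    ])


@pytest.fixture
def small_series(small_panel):
    # alpha: D1-D4 pulse peaking D2; beta: low-level D2-D3; gamma: D2 only;
    # delta: D4 only (no LD50)
    return make_series({
        1: {"alpha": 10.0},
        2: {"alpha": 100.0, "beta": 4.0, "gamma": 20.0},
        3: {"alpha": 30.0, "beta": 5.0},
        4: {"alpha": 6.0, "delta": 12.0},
        5: {},
    }, small_panel)


@pytest.fixture(scope="session")
def study_panel():
    from pollenhq.datasets import load_panel

    return load_panel()


@pytest.fixture(scope="session")
def study_table():
    from pollenhq.datasets import load_panel_table

    return load_panel_table()
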