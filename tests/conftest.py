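import numpy as np
import pandas as pd
import pytest

from rhythmkit.io import ParticipantSeries


def make_series(steps, heart_rate, start="2024-03-04", pid="T01"):
    """Canonical series from raw arrays (NaN = missing); HR gaps mask steps."""
    steps = np.asarray(steps, dtype=float)
    hr = np.asarray(heart_rate, dtype=float)
    assert len(steps) == len(hr)
    index = pd.date_range(start, periods=len(steps), freq="min")
    df = pd.DataFrame({"steps": steps, "heart_rate": hr}, index=index)
    df.loc[df["heart_rate"].isna(), "steps"] = np.nan
    df["valid"] = df["steps"].notna() & df["heart_rate"].notna()
    return ParticipantSeries(participant_id=pid, data=df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)
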