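"""Validity rules and hourly aggregation for wearable minute streams.

A calendar day is *valid* when it holds at least 20 hours of concurrent step
and heart-rate data; a participant is *included* when at least 5 days are
valid.  Hourly aggregates keep a clock-hour cell only when the hour contains
at least 30 valid minutes; hourly step sums are rescaled to a full hour
(60 / valid minutes) so partially worn hours are not biased low, hourly heart
rate is the mean of valid minutes.  All downstream rhythm and heart-rate
metrics consume only valid days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ParticipantSeries

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    valid_day_hours: float = 20.0  # concurrent hours for a valid day
    min_valid_days: int = 5        # valid days for inclusion
    hour_min_minutes: int = 30     # valid minutes for an hourly cell
    rescale_partial_hours: bool = True  # scale hourly step sums by 60/valid


@dataclass
class ValidDaySet:
    """Day-indexed validity flags and hourly aggregates for one participant."""

    participant_id: str
    days: list  # calendar dates (datetime.date), one per recorded day
    valid_hours_per_day: np.ndarray  # hours of concurrent data per day
    day_valid: np.ndarray  # bool per day
    included: bool
    hourly_steps: np.ndarray | None = field(default=None, repr=False)  # day x 24
    hourly_hr: np.ndarray | None = field(default=None, repr=False)  # day x 24
    hourly_valid_minutes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_valid_days(self) -> int:
        return int(self.day_valid.sum())

    def valid_hourly(self, stream: str) -> np.ndarray:
        """Hourly matrix restricted to valid days (rows in time order)."""
        mat = self.hourly_steps if stream == "steps" else self.hourly_hr
        if mat is None:
            raise ValueError("hourly aggregates not computed; call hourly_aggregate")
        return mat[self.day_valid]


def _day_hour_frame(series: ParticipantSeries) -> pd.DataFrame:
    df = series.data
    return pd.DataFrame(
        {
            "date": df.index.normalize(),
            "hour": df.index.hour,
            "steps": df["steps"].to_numpy(),
            "heart_rate": df["heart_rate"].to_numpy(),
            "valid": df["valid"].to_numpy(),
        }
    )


def compute_valid_days(
    series: ParticipantSeries, config: PreprocessConfig | None = None
) -> ValidDaySet:
    """Apply the >=20 h concurrency rule per day and the >=5-day inclusion rule."""
    config = config or PreprocessConfig()
    frame = _day_hour_frame(series)
    per_day = frame.groupby("date", sort=True)["valid"].sum()
    days = [d.date() for d in per_day.index]
    valid_hours = per_day.to_numpy(dtype=float) / 60.0
    day_valid = valid_hours >= config.valid_day_hours
    included = int(day_valid.sum()) >= config.min_valid_days
    return ValidDaySet(
        participant_id=series.participant_id,
        days=days,
        valid_hours_per_day=valid_hours,
        day_valid=day_valid,
        included=included,
    )


def hourly_aggregate(
    series: ParticipantSeries,
    day_set: ValidDaySet,
    config: PreprocessConfig | None = None,
) -> ValidDaySet:
    """Fill the day x 24 hourly step/heart-rate matrices in ``day_set``.

    Cells with fewer than ``hour_min_minutes`` valid minutes are missing.
    """
    config = config or PreprocessConfig()
    if day_set.participant_id != series.participant_id:
        raise ValueError("day_set belongs to a different participant")
    frame = _day_hour_frame(series)
    frame = frame[frame["valid"]]
    n_days = len(day_set.days)
    steps_mat = np.full((n_days, 24), np.nan)
    hr_mat = np.full((n_days, 24), np.nan)
    minutes_mat = np.zeros((n_days, 24), dtype=int)
    day_pos = {d: i for i, d in enumerate(day_set.days)}

    grouped = frame.groupby([frame["date"].dt.date, "hour"])
    agg = grouped.agg(
        n=("valid", "size"), step_sum=("steps", "sum"), hr_mean=("heart_rate", "mean")
    )
    for (date, hour), row in agg.iterrows():
        i = day_pos[date]
        n = int(row["n"])
        minutes_mat[i, hour] = n
        if n >= config.hour_min_minutes:
            scale = 60.0 / n if config.rescale_partial_hours else 1.0
            steps_mat[i, hour] = row["step_sum"] * scale
            hr_mat[i, hour] = row["hr_mean"]
    day_set.hourly_steps = steps_mat
    day_set.hourly_hr = hr_mat
    day_set.hourly_valid_minutes = minutes_mat
    return day_set


def preprocess(
    series: ParticipantSeries, config: PreprocessConfig | None = None
) -> ValidDaySet:
    """Convenience: validity rules plus hourly aggregation in one call."""
    config = config or PreprocessConfig()
    return hourly_aggregate(series, compute_valid_days(series, config), config)


def mean_24h_profile(day_set: ValidDaySet, stream: str) -> tuple[np.ndarray, np.ndarray]:
    """Across-valid-day mean and sample SD of the hourly aggregate, per clock hour.

    Hours with no valid cells are missing; hours with a single cell have
    missing SD.
    """
    mat = day_set.valid_hourly(stream)
    mean = np.full(24, np.nan)
    sd = np.full(24, np.nan)
    for h in range(24):
        col = mat[:, h]
        col = col[~np.isnan(col)]
        if len(col) >= 1:
            mean[h] = col.mean()
        if len(col) >= 2:
            sd[h] = np.std(col, ddof=1)
    return mean, sd


def restrict_to_valid_days(series: ParticipantSeries, day_set: ValidDaySet) -> pd.DataFrame:
    """Minute frame with all minutes of invalid days forced to missing."""
    df = series.data.copy()
    valid_dates = {d for d, ok in zip(day_set.days, day_set.day_valid) if ok}
    on_valid = np.array([d in valid_dates for d in df.index.date])
    df.loc[~on_valid, ["steps", "heart_rate"]] = np.nan
    df.loc[~on_valid, "valid"] = False
    return df
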