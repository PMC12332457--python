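"""Heart-rate biomarker family.

All quantities are computed over valid minutes of valid days only:

* overall mean / SD / CV of minute heart rate;
* RHR — mean heart rate inside 15-minute blocks (aligned to :00/:15/:30/:45)
  whose minutes are all valid and all have zero steps;
* dRHR = overall mean - RHR, the activity-rest heart-rate contrast;
* daytime HR (14:00-16:00) and nighttime HR (unweighted mean of the
  00-02, 02-04 and 04-06 window means);
* RMSSD on raw minute samples and on the hourly means (adjacent clock hours
  of the same day), with pairs spanning a gap excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import ValidDaySet

logger = logging.getLogger(__name__)


@dataclass
class RestConfig:
    block_minutes: int = 15
    require_complete: bool = True  # all block minutes valid (config relaxation)
    min_block_minutes: int = 1     # used only when require_complete is False


def resting_heart_rate(
    minute_frame: pd.DataFrame, config: RestConfig | None = None
) -> float:
    """Mean HR over all minutes of qualifying zero-step 15-minute blocks.

    ``minute_frame`` is a valid-day-restricted canonical minute frame.  A
    block qualifies iff every minute is valid and every step count is 0
    (strict completeness by default).
    """
    config = config or RestConfig()
    bm = config.block_minutes
    valid = minute_frame["valid"].to_numpy()
    steps = minute_frame["steps"].to_numpy()
    hr = minute_frame["heart_rate"].to_numpy()
    # anchor blocks to clock multiples of block_minutes (:00/:15/:30/:45)
    first = minute_frame.index[0]
    offset = (first.hour * 60 + first.minute) % bm
    block = (np.arange(len(minute_frame)) + offset) // bm

    n_blocks = block[-1] + 1
    size = np.bincount(block, minlength=n_blocks)
    n_valid = np.bincount(block, weights=valid, minlength=n_blocks)
    zero_step = valid & (steps == 0)
    n_zero = np.bincount(block, weights=zero_step, minlength=n_blocks)
    if config.require_complete:
        qualifies = (size == bm) & (n_valid == bm) & (n_zero == bm)
    else:
        qualifies = (n_valid >= config.min_block_minutes) & (n_zero == n_valid)
    sel = qualifies[block] & valid
    if not sel.any():
        logger.info("RHR undefined: no qualifying zero-step block")
        return np.nan
    return float(hr[sel].mean())


def delta_rhr(hr_mean: float, rhr: float) -> float:
    """dRHR = overall mean heart rate minus resting heart rate."""
    return hr_mean - rhr


def day_night_hr(minute_frame: pd.DataFrame) -> dict[str, float]:
    """Daytime (14-16 h) and nighttime (mean of 0-2, 2-4, 4-6 h windows) HR."""
    hours = minute_frame.index.hour.to_numpy()
    valid = minute_frame["valid"].to_numpy()
    hr = minute_frame["heart_rate"].to_numpy()

    def window_mean(lo: int, hi: int) -> float:
        sel = (hours >= lo) & (hours < hi) & valid
        if not sel.any():
            logger.info("HR window %d-%d empty", lo, hi)
            return np.nan
        return float(hr[sel].mean())

    day = window_mean(14, 16)
    windows = [window_mean(0, 2), window_mean(2, 4), window_mean(4, 6)]
    night = float(np.mean(windows)) if not np.isnan(windows).any() else np.nan
    return {
        "day_hr": day,
        "night_hr": night,
        "night_hr_windows": windows,
    }


def rmssd(values: np.ndarray, adjacency: np.ndarray | None = None) -> float:
    """Root mean square of successive differences over present pairs.

    ``adjacency[i]`` (optional) marks whether sample ``i`` genuinely follows
    sample ``i-1`` in time; pairs spanning a gap are excluded.  NaN samples
    break pairs as well.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.nan
    a, b = values[:-1], values[1:]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if adjacency is not None:
        ok &= np.asarray(adjacency, dtype=bool)[1:]
    if ok.sum() < 1:
        logger.info("RMSSD undefined: no usable successive pair")
        return np.nan
    d = b[ok] - a[ok]
    return float(np.sqrt(np.mean(d * d)))


def rmssd_hourly(day_set: ValidDaySet) -> float:
    """RMSSD over the valid-day hourly HR means, adjacent clock hours of the
    same day only."""
    mat = day_set.valid_hourly("heart_rate")
    values = mat.reshape(-1)
    # same-day adjacency: hour h follows h-1 unless h == 0 (row boundary)
    adjacency = np.ones(values.shape, dtype=bool)
    adjacency[::24] = False
    return rmssd(values, adjacency)


def heart_rate_features(
    minute_frame: pd.DataFrame,
    day_set: ValidDaySet,
    rest_config: RestConfig | None = None,
) -> dict[str, float]:
    """The full heart-rate feature family for one included participant.

    ``minute_frame`` must already be restricted to valid days (invalid days
    masked); see :func:`rhythmkit.preprocessing.restrict_to_valid_days`.
    """
    valid = minute_frame["valid"].to_numpy()
    hr = minute_frame["heart_rate"].to_numpy()[valid]
    if len(hr) == 0:
        nan = np.nan
        return {k: nan for k in (
            "HR.mean", "HR.sd", "HR.cv", "RHR", "dRHR", "DHR", "NHR",
            "NHR.w1", "NHR.w2", "NHR.w3", "RMSSD.raw", "RMSSD.hourly",
        )}
    hr_mean = float(hr.mean())
    hr_sd = float(hr.std(ddof=1)) if len(hr) >= 2 else np.nan
    rhr = resting_heart_rate(minute_frame, rest_config)
    dn = day_night_hr(minute_frame)
    masked_hr = np.where(minute_frame["valid"].to_numpy(), minute_frame["heart_rate"].to_numpy(), np.nan)
    return {
        "HR.mean": hr_mean,
        "HR.sd": hr_sd,
        "HR.cv": hr_sd / hr_mean if hr_mean > 0 else np.nan,
        "RHR": rhr,
        "dRHR": delta_rhr(hr_mean, rhr),
        "DHR": dn["day_hr"],
        "NHR": dn["night_hr"],
        "NHR.w1": dn["night_hr_windows"][0],
        "NHR.w2": dn["night_hr_windows"][1],
        "NHR.w3": dn["night_hr_windows"][2],
        "RMSSD.raw": rmssd(masked_hr),
        "RMSSD.hourly": rmssd_hourly(day_set),
    }
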