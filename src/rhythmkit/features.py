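"""Per-participant biomarker extraction: one wide row per participant.

Combines the three metric families on both streams.  Step-based and
heart-rate-based variants share code; columns carry ``.st`` / ``.hr``
suffixes.  The extended cosinor is fitted to minute-level heart rate and —
to tame zero-inflation — to hourly step aggregates (configurable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import nonparametric as npar
from .cosinor import fit_extended_cosinor
from .hr import RestConfig, heart_rate_features
from .io import ParticipantSeries
from .preprocessing import (
    PreprocessConfig,
    ValidDaySet,
    mean_24h_profile,
    preprocess,
    restrict_to_valid_days,
)

logger = logging.getLogger(__name__)

FAMILIES = ("nonparametric", "cosinor", "hr")
_STREAMS = {"steps": "st", "heart_rate": "hr"}

_COSINOR_FIELDS = {
    "Minimum": "minimum",
    "Amplitude": "amplitude",
    "alpha": "alpha",
    "beta": "beta",
    "Acrotime": "acrotime",
    "F_pseudo": "f_pseudo",
    "UpMesor": "up_mesor",
    "DownMesor": "down_mesor",
    "MESOR": "mesor",
}


def _nonparametric_family(
    restricted: pd.DataFrame,
    day_set: ValidDaySet,
    stream: str,
    peak_config: npar.PeakConfig | None,
) -> dict[str, float]:
    sfx = _STREAMS[stream]
    hourly = day_set.valid_hourly(stream)
    dates = [d for d, ok in zip(day_set.days, day_set.day_valid) if ok]
    profile, _ = mean_24h_profile(day_set, stream)
    windows = npar.m10_l5_ra(profile)
    masked = np.where(
        restricted["valid"].to_numpy(), restricted[stream].to_numpy(), np.nan
    )
    day_index = restricted.index.date
    peaks_mean, peaks_sd = npar.robust_peak_counts(masked, day_index, peak_config)
    out = {
        f"IS.{sfx}": npar.interdaily_stability(hourly),
        f"IV.{sfx}": npar.intradaily_variability(hourly, dates),
        f"M10.{sfx}": windows["M10"],
        f"L5.{sfx}": windows["L5"],
        f"RA.{sfx}": windows["RA"],
        f"ICV.{sfx}": npar.intradaily_cv(hourly),
        f"Peaks.{sfx}.mean": peaks_mean,
        f"Peaks.{sfx}.sd": peaks_sd,
    }
    for bin_minutes in (60, 30, 15):
        out[f"AC.{sfx}.{bin_minutes}m"] = npar.day_lag_autocorrelation(
            masked, bin_minutes
        )
    return out


def _cosinor_family(
    restricted: pd.DataFrame,
    day_set: ValidDaySet,
    stream: str,
    steps_resolution: str,
) -> dict[str, float]:
    sfx = _STREAMS[stream]
    if stream == "steps" and steps_resolution == "hourly":
        mat = day_set.valid_hourly(stream)
        t = np.tile(np.arange(24) + 0.5, mat.shape[0])
        values = mat.reshape(-1)
    else:
        idx = restricted.index
        t = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
        values = np.where(
            restricted["valid"].to_numpy(), restricted[stream].to_numpy(), np.nan
        )
    fit = fit_extended_cosinor(t, values)
    return {f"{name}.{sfx}": getattr(fit, attr) for name, attr in _COSINOR_FIELDS.items()}


def extract_features(
    series: ParticipantSeries,
    config: PreprocessConfig | None = None,
    families: tuple[str, ...] = FAMILIES,
    peak_config: npar.PeakConfig | None = None,
    rest_config: RestConfig | None = None,
    cosinor_steps_resolution: str = "hourly",
) -> dict[str, float]:
    """The full per-participant feature vector (wide-row dict).

    Participants failing the inclusion rule return only the bookkeeping
    columns (``included`` False); metric columns are omitted and appear as
    missing when rows are stacked into a cohort table.
    """
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    day_set = preprocess(series, config)
    out: dict[str, float] = {
        "participant_id": series.participant_id,
        "included": day_set.included,
        "n_valid_days": day_set.n_valid_days,
    }
    if not day_set.included:
        return out
    restricted = restrict_to_valid_days(series, day_set)

    # mean daily step total over valid days (raw valid-minute sums)
    per_day = restricted.loc[restricted["valid"], "steps"].groupby(
        restricted.index[restricted["valid"].to_numpy()].date
    ).sum()
    out["Steps"] = float(per_day.mean()) if len(per_day) else np.nan

    if "nonparametric" in families:
        for stream in _STREAMS:
            out.update(_nonparametric_family(restricted, day_set, stream, peak_config))
    if "cosinor" in families:
        for stream in _STREAMS:
            out.update(
                _cosinor_family(restricted, day_set, stream, cosinor_steps_resolution)
            )
    if "hr" in families:
        out.update(heart_rate_features(restricted, day_set, rest_config))
    return out


def extract_cohort_features(
    series_map: dict[str, ParticipantSeries],
    config: PreprocessConfig | None = None,
    families: tuple[str, ...] = FAMILIES,
    **kwargs,
) -> pd.DataFrame:
    """Stack per-participant feature rows into a cohort table."""
    rows = [
        extract_features(s, config=config, families=families, **kwargs)
        for s in series_map.values()
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        n_excluded = int((~df["included"]).sum())
        if n_excluded:
            logger.info(
                "extract_cohort_features: %d of %d participants lack 5 valid days",
                n_excluded, len(df),
            )
    return df
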