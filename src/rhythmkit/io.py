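"""Reading, validation and canonicalization of minute-level wearable streams.

The canonical in-memory object is :class:`ParticipantSeries`: a gap-free,
minute-indexed frame of step counts and heart rate for one participant, with
a per-minute validity mask that is true exactly where *both* streams carry a
measurement.  Minutes with absent heart rate have their step count forced to
missing, because a step value recorded while the optical sensor was off the
wrist is not trustworthy.

Two file dialects are supported:

``long_csv``
    ``participant_id,timestamp,steps,heart_rate`` with ISO-8601 minute
    timestamps, one row per observed minute.  Gzip-compressed files are read
    transparently (by extension).

``fitbit_json``
    A list of participant objects shaped like intraday API payloads::

        [{"participant_id": "P01",
          "days": [{"date": "2024-01-01",
                    "steps":      [{"time": "00:00", "value": 0}, ...],
                    "heart_rate": [{"time": "00:00", "value": 62}, ...]}]}]

Timestamps are naive local time; the calendar-day boundary is local
midnight.  A heart rate of 0 is treated as a sensor gap, not a measurement.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTE_COLUMNS = ["participant_id", "timestamp", "steps", "heart_rate"]

QUESTIONNAIRE_ITEMS = [
    "living_alone",
    "no_daily_conversation",
    "not_feeling_helpful",
    "going_out_less",
    "not_visiting_friends",
]

QUESTIONNAIRE_COLUMNS = (
    ["participant_id", "age", "sex"]
    + QUESTIONNAIRE_ITEMS
    + ["grip_strength", "walking_speed", "wlm", "tmt_a", "tmt_b", "dsst"]
)


class WearableIOError(ValueError):
    """Malformed or invalid wearable input."""


@dataclass
class ParticipantSeries:
    """Gap-free minute-indexed step/heart-rate streams for one participant.

    ``data`` is indexed by minute timestamps (strictly increasing, no gaps)
    with float columns ``steps`` and ``heart_rate`` (NaN = missing) and a
    boolean column ``valid`` (both streams present).
    """

    participant_id: str
    data: pd.DataFrame = field(repr=False)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data["valid"].to_numpy()

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == 60_000_000_000):
                raise WearableIOError(
                    f"participant {self.participant_id}: canonical series must "
                    "be gap-free at minute resolution"
                )


@dataclass
class QuestionnaireRecord:
    """One participant's questionnaire row: demographics, the five social
    frailty items (1 = risk present), physical and cognitive scores."""

    participant_id: str
    age: float
    sex: str  # "female" | "male"
    frailty_items: dict[str, float]  # item name -> 0/1 (NaN allowed)
    grip_strength: float
    walking_speed: float
    wlm: float
    tmt_a: float
    tmt_b: float
    dsst: float


def _canonicalize(pid: str, frame: pd.DataFrame) -> ParticipantSeries:
    """Sort, truncate to minutes, check duplicates, materialize gaps, mask."""
    ts = frame["timestamp"].dt.floor("min")
    dup = ts.duplicated(keep=False)
    if dup.any():
        dups = sorted(ts[dup].dt.strftime("%Y-%m-%dT%H:%M").unique())
        raise WearableIOError(
            f"participant {pid}: duplicate minutes {', '.join(dups[:10])}"
        )
    steps = pd.to_numeric(frame["steps"], errors="coerce").astype(float)
    if (steps.dropna() < 0).any():
        raise WearableIOError(f"participant {pid}: negative step counts")
    hr = pd.to_numeric(frame["heart_rate"], errors="coerce").astype(float)
    hr = hr.where(hr > 0)  # HR <= 0 is a gap, not a measurement

    df = pd.DataFrame({"steps": steps.values, "heart_rate": hr.values}, index=ts.values)
    df = df.sort_index()
    full = pd.date_range(df.index[0], df.index[-1], freq="min")
    df = df.reindex(full)
    # steps recorded while HR is absent are marked invalid (forced missing)
    df.loc[df["heart_rate"].isna(), "steps"] = np.nan
    df["valid"] = df["steps"].notna() & df["heart_rate"].notna()
    return ParticipantSeries(participant_id=pid, data=df)


def _read_long_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MINUTE_COLUMNS if c not in raw.columns]
    if missing:
        raise WearableIOError(f"{path}: missing required columns {missing}")
    try:
        raw["timestamp"] = pd.to_datetime(raw["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = None
        parsed = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
        if parsed.isna().any():
            bad = int(parsed.isna().idxmax()) + 2  # 1-based incl. header
        raise WearableIOError(f"{path}: malformed timestamp at row {bad}") from exc
    return raw


def _read_fitbit_json(path) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        payload = json.load(fh)
    rows: list[tuple] = []
    for part in payload:
        pid = str(part["participant_id"])
        for day in part.get("days", []):
            date = day["date"]
            merged: dict[str, dict[str, float]] = {}
            for stream in ("steps", "heart_rate"):
                for item in day.get(stream, []):
                    key = item["time"][:5]
                    slot = merged.setdefault(key, {})
                    # duplicate API samples: first observation wins
                    slot.setdefault(stream, item["value"])
            for hhmm, values in merged.items():
                try:
                    ts = pd.Timestamp(f"{date} {hhmm}")
                except ValueError as exc:
                    raise WearableIOError(
                        f"{path}: malformed time {date} {hhmm!r} for {pid}"
                    ) from exc
                rows.append(
                    (pid, ts, values.get("steps", np.nan), values.get("heart_rate", np.nan))
                )
    return pd.DataFrame(rows, columns=MINUTE_COLUMNS)


def read_minute_table(path, dialect: str = "long_csv") -> dict[str, ParticipantSeries]:
    """Read a minute-level step/heart-rate table into canonical series.

    Returns an insertion-ordered mapping of participant id to
    :class:`ParticipantSeries`.  An empty file yields an empty mapping with a
    logged warning.
    """
    if dialect == "long_csv":
        raw = _read_long_csv(path)
    elif dialect == "fitbit_json":
        raw = _read_fitbit_json(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if raw.empty:
        logger.warning("%s: no rows, returning empty collection", path)
        return {}
    out: dict[str, ParticipantSeries] = {}
    for pid, frame in raw.groupby("participant_id", sort=False):
        out[str(pid)] = _canonicalize(str(pid), frame)
    return out


def write_minute_table(series: dict[str, ParticipantSeries] | ParticipantSeries, path) -> None:
    """Write canonical series back to the long CSV dialect (byte-stable)."""
    if isinstance(series, ParticipantSeries):
        series = {series.participant_id: series}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", newline="") as fh:
        fh.write(",".join(MINUTE_COLUMNS) + "\n")
        for pid, s in series.items():
            stamps = s.data.index.strftime("%Y-%m-%dT%H:%M")
            steps = s.data["steps"].to_numpy()
            hr = s.data["heart_rate"].to_numpy()
            for ts, st, h in zip(stamps, steps, hr):
                st_s = "" if np.isnan(st) else str(int(st))
                hr_s = "" if np.isnan(h) else f"{h:g}"
                fh.write(f"{pid},{ts},{st_s},{hr_s}\n")


def read_questionnaire(path) -> list[QuestionnaireRecord]:
    """Read the questionnaire CSV into typed records.

    Validates the social-frailty items (0/1) and the word-list-memory score
    (0-20).  Participant ids not present in the wearable store are allowed;
    the join happens later in the analysis layer.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in raw.columns]
    if missing:
        raise WearableIOError(f"{path}: missing questionnaire columns {missing}")
    records = []
    for i, row in raw.iterrows():
        wlm = float(row["wlm"])
        if not np.isnan(wlm) and not 0 <= wlm <= 20:
            raise WearableIOError(
                f"{path}: WLM score {wlm} outside 0-20 at row {i + 2}"
            )
        items = {}
        for item in QUESTIONNAIRE_ITEMS:
            v = float(row[item]) if pd.notna(row[item]) else np.nan
            if not np.isnan(v) and v not in (0.0, 1.0):
                raise WearableIOError(
                    f"{path}: frailty item {item}={v} not 0/1 at row {i + 2}"
                )
            items[item] = v
        records.append(
            QuestionnaireRecord(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                frailty_items=items,
                grip_strength=float(row["grip_strength"]),
                walking_speed=float(row["walking_speed"]),
                wlm=wlm,
                tmt_a=float(row["tmt_a"]),
                tmt_b=float(row["tmt_b"]),
                dsst=float(row["dsst"]),
            )
        )
    return records
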