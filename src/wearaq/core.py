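"""Shared data model for wearable air-quality campaigns.

All timestamps are stored timezone-aware in UTC.  Clock-local logic (the
overnight home-identification rule, the night structure of simulated
schedules) converts on the fly using a per-participant timezone that
defaults to Europe/Paris.

Missing measurements are NaN; they are never encoded as 0 or a sentinel.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("wearaq")

#: The seven measured channels, in canonical order.
CHANNELS = ("temperature", "humidity", "pm1", "pm25", "pm10", "no2", "bc")

#: Channels of the fused per-minute table (measurements + GPS-derived speed).
FUSED_CHANNELS = CHANNELS + ("speed",)

#: The three nested particulate-matter channels, finest first.
PM_CHANNELS = ("pm1", "pm25", "pm10")

#: Microenvironment vocabulary.
ENVIRONMENTS = ("home", "office", "indoor", "outdoor", "transport")

CHANNEL_UNITS = {
    "temperature": "degC",
    "humidity": "%RH",
    "pm1": "ug/m3",
    "pm25": "ug/m3",
    "pm10": "ug/m3",
    "no2": "ug/m3",
    "bc": "ng/m3",
    "speed": "km/h",
}

DEFAULT_TZ = "Europe/Paris"

FUSED_COLUMNS = list(FUSED_CHANNELS) + ["lon", "lat", "label"]


class WearaqError(Exception):
    """Base class for package errors."""


class ParseError(WearaqError, ValueError):
    """A file could not be parsed (malformed timestamp, bad geometry...)."""


class ConfigError(WearaqError, ValueError):
    """An invalid configuration value."""


class ValidationError(WearaqError, ValueError):
    """A data-model invariant is violated."""


def _to_utc_index(values) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(values)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    return idx.rename(None)


@dataclass
class SensorSeries:
    """One channel's per-minute time series.

    ``data`` is a float Series indexed by a strictly increasing UTC
    DatetimeIndex with >= 1 minute spacing; NaN marks a missing value.
    """

    channel: str
    data: pd.Series
    participant_id: str = ""
    sensor_id: str = ""

    def __post_init__(self):
        if self.channel not in FUSED_CHANNELS:
            raise ConfigError(f"unknown channel {self.channel!r}")
        s = pd.Series(np.asarray(self.data.values, dtype=float),
                      index=_to_utc_index(self.data.index), name=self.channel)
        self.data = s
        self.validate()

    def validate(self) -> None:
        idx = self.data.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if (deltas <= 0).any():
                raise ValidationError(
                    f"{self.channel}: timestamps not strictly increasing")
            if (deltas < 60 * 10**9).any():
                raise ValidationError(
                    f"{self.channel}: spacing below one minute")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def replace(self, data: pd.Series) -> "SensorSeries":
        return dataclasses.replace(self, data=data)


def minute_align(timestamps, values, channel: str, participant_id: str = "",
                 sensor_id: str = "") -> SensorSeries:
    """Floor timestamps to the containing minute and average within minutes.

    This is how raw (possibly sub-minute, possibly duplicated) samples are
    brought onto the canonical one-minute grid.
    """
    idx = _to_utc_index(timestamps)
    s = pd.Series(np.asarray(values, dtype=float), index=idx.floor("min"))
    s = s.groupby(level=0).mean().sort_index()
    return SensorSeries(channel=channel, data=s,
                        participant_id=participant_id, sensor_id=sensor_id)


@dataclass
class GpsTrack:
    """Timestamped WGS84 positions (lon/lat decimal degrees).

    Sub-minute sampling is allowed; timestamps are non-decreasing.
    """

    data: pd.DataFrame  # columns lon, lat; UTC DatetimeIndex
    participant_id: str = ""

    def __post_init__(self):
        df = self.data[["lon", "lat"]].astype(float).copy()
        df.index = _to_utc_index(self.data.index)
        df = df.sort_index()
        self.data = df
        self.validate()

    def validate(self) -> None:
        lon = self.data["lon"].to_numpy()
        lat = self.data["lat"].to_numpy()
        if np.any((lat < -90) | (lat > 90)):
            raise ValidationError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValidationError("longitude outside [-180, 180]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index


@dataclass
class FusedTable:
    """Per-minute multi-channel table, the pipeline's central container.

    A row exists only if at least one of the seven measured channels is
    present; GPS position or derived speed alone does not make a row.
    Where all three PM channels are present they must be nested
    (pm1 <= pm25 <= pm10).
    """

    frame: pd.DataFrame
    participant_id: str = ""
    tz: str = DEFAULT_TZ

    def __post_init__(self):
        df = self.frame.copy()
        df.index = _to_utc_index(df.index)
        for col in FUSED_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "label" else None
        num = [c for c in FUSED_COLUMNS if c != "label"]
        df[num] = df[num].astype(float)
        df["label"] = df["label"].astype(object).where(df["label"].notna(), None)
        df = df[FUSED_COLUMNS].sort_index()
        self.frame = df
        self.validate()

    def validate(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            raise ValidationError("duplicate minutes in fused table")
        if len(df) and df[list(CHANNELS)].isna().all(axis=1).any():
            raise ValidationError(
                "fused row without any sensor measurement")
        pm = df[list(PM_CHANNELS)]
        full = pm.notna().all(axis=1)
        if full.any():
            sub = pm[full]
            ok = (sub["pm1"] <= sub["pm25"]) & (sub["pm25"] <= sub["pm10"])
            if not ok.all():
                raise ValidationError("PM ordering pm1<=pm25<=pm10 violated")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def with_labels(self, labels: pd.Series) -> "FusedTable":
        df = self.frame.copy()
        df["label"] = labels.reindex(df.index)
        return dataclasses.replace(self, frame=df)


@dataclass
class AnnotationSet:
    """Ground-truth environment intervals [start, end) for one participant."""

    intervals: pd.DataFrame  # columns start, end, label
    participant_id: str = ""

    def __post_init__(self):
        df = self.intervals.copy()
        df["start"] = _to_utc_index(df["start"])
        df["end"] = _to_utc_index(df["end"])
        df["label"] = df["label"].astype(str)
        df = df.sort_values("start").reset_index(drop=True)
        self.intervals = df
        self.validate()

    def validate(self) -> None:
        df = self.intervals
        bad = set(df["label"]) - set(ENVIRONMENTS)
        if bad:
            raise ValidationError(f"unknown environment labels: {sorted(bad)}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("annotation interval with start >= end")
        if len(df) > 1 and (df["start"].values[1:] < df["end"].values[:-1]).any():
            raise ValidationError("overlapping annotation intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def label_minutes(self, index: pd.DatetimeIndex) -> pd.Series:
        """Label each minute by its covering interval (start incl., end excl.)."""
        out = pd.Series([None] * len(index), index=index, dtype=object)
        for start, end, label in self.intervals.itertuples(index=False):
            out[(index >= start) & (index < end)] = label
        return out
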