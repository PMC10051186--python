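"""Readers and writers for the on-disk artifacts.

Conventions (this package's own, the field has no standard here):

* per-channel sensor CSV: header ``timestamp,value``, ISO-8601 timestamps;
* GPS as CSV ``timestamp,lon,lat`` or GeoJSON (Point features with a
  ``time`` property, or a LineString with per-point ``times``);
* fused table CSV with fixed header
  ``timestamp,temperature,humidity,pm1,pm25,pm10,no2,bc,speed,lon,lat,label``;
* annotations CSV ``start,end,label``.

Missing values are empty fields.  Readers never silently drop rows: the only
lossy steps are exact-duplicate-timestamp deduplication (keep last) and
within-minute averaging, both logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (AnnotationSet, ConfigError, FusedTable, FUSED_COLUMNS,
                   GpsTrack, CHANNELS, ParseError, SensorSeries, minute_align)

logger = logging.getLogger("wearaq")

_TS_FMT = "%Y-%m-%dT%H:%M:%S%z"


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(f"{path}: malformed timestamp at line {line}: "
                         f"{raw[bad].iloc[0]!r}")
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise ParseError(f"{path}: empty timestamp at line {line}")
    return pd.DatetimeIndex(parsed)


def read_sensor_csv(path, channel: str) -> SensorSeries:
    """Read one channel's ``timestamp,value`` CSV onto the minute grid.

    Exact duplicate timestamps keep the last occurrence (count logged);
    distinct sub-minute samples within one minute are averaged.
    """
    if channel not in CHANNELS:
        raise ConfigError(f"unknown channel {channel!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"timestamp": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if not {"timestamp", "value"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns timestamp,value")
    ts = _parse_timestamps(df["timestamp"], path)
    vals = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    order = np.argsort(ts.asi8, kind="stable")
    ts, vals = ts[order], vals[order]
    dup = pd.Index(ts).duplicated(keep="last")
    if dup.any():
        logger.info("%s: dropped %d duplicate-timestamp rows (kept last)",
                    path, int(dup.sum()))
    return minute_align(ts[~dup], vals[~dup], channel)


def read_gps(path, dialect: str = "csv") -> GpsTrack:
    """Read a GPS track from CSV (``timestamp,lon,lat``) or GeoJSON."""
    path = Path(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path, dtype={"timestamp": str})
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        if not {"timestamp", "lon", "lat"} <= set(df.columns):
            raise ParseError(f"{path}: expected columns timestamp,lon,lat")
        ts = _parse_timestamps(df["timestamp"], path)
        frame = pd.DataFrame(
            {"lon": pd.to_numeric(df["lon"]).to_numpy(),
             "lat": pd.to_numeric(df["lat"]).to_numpy()}, index=ts)
    elif dialect == "geojson":
        obj = json.loads(path.read_text())
        times, lons, lats = [], [], []
        features = obj.get("features", [obj] if obj.get("type") == "Feature" else [])
        if not features:
            raise ParseError(f"{path}: no GeoJSON features")
        for feat in features:
            geom = feat.get("geometry")
            if not geom:
                raise ParseError(f"{path}: feature without geometry")
            props = feat.get("properties") or {}
            if geom["type"] == "Point":
                if "time" not in props:
                    raise ParseError(f"{path}: Point feature without 'time'")
                lon, lat = geom["coordinates"][:2]
                times.append(props["time"]); lons.append(lon); lats.append(lat)
            elif geom["type"] == "LineString":
                tlist = props.get("times") or props.get("time")
                coords = geom["coordinates"]
                if not tlist or len(tlist) != len(coords):
                    raise ParseError(
                        f"{path}: LineString needs per-point 'times'")
                for t, c in zip(tlist, coords):
                    times.append(t); lons.append(c[0]); lats.append(c[1])
            else:
                raise ParseError(f"{path}: unsupported geometry {geom['type']}")
        ts = _parse_timestamps(pd.Series(times, dtype=str), path)
        frame = pd.DataFrame({"lon": lons, "lat": lats}, index=ts)
    else:
        raise ConfigError(f"unknown GPS dialect {dialect!r}")
    return GpsTrack(frame)


def write_fused_table(table: FusedTable, path) -> None:
    table.validate()
    df = table.frame.copy()
    df.index = df.index.strftime(_TS_FMT)
    df.index.name = "timestamp"
    df.to_csv(path, na_rep="")


def read_fused_table(path) -> FusedTable:
    path = Path(path)
    df = pd.read_csv(path, dtype={"timestamp": str, "label": str})
    missing = set(FUSED_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ts = _parse_timestamps(df["timestamp"], path)
    df = df.drop(columns=["timestamp"]).set_index(ts)
    return FusedTable(df)


def write_annotations(ann: AnnotationSet, path) -> None:
    df = ann.intervals.copy()
    df["start"] = df["start"].dt.strftime(_TS_FMT)
    df["end"] = df["end"].dt.strftime(_TS_FMT)
    df.to_csv(path, index=False)


def read_annotations(path, participant_id: str = "") -> AnnotationSet:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if not {"start", "end", "label"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns start,end,label")
    return AnnotationSet(df[["start", "end", "label"]],
                         participant_id=participant_id)


def write_sensor_csv(series: SensorSeries, path) -> None:
    df = pd.DataFrame({"timestamp": series.timestamps.strftime(_TS_FMT),
                       "value": series.values})
    df.to_csv(path, index=False)


def write_gps_csv(track: GpsTrack, path) -> None:
    df = track.data.copy()
    df.index = df.index.strftime(_TS_FMT)
    df.index.name = "timestamp"
    df.to_csv(path)
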